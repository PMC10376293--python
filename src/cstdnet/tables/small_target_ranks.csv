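model,P,R,F1,AP
CenterNet,3,4,4,4
SSD,2,6,6,6
FCOS,5,3,3,3
YOLOV5,6,5,5,5
YOLOV7,4,2,2,2
Ours,1,1,1,1
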