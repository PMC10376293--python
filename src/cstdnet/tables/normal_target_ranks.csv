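model,P,R,F1,AP
CenterNet,6,5,5,5
SSD,5,6,6,6
FCOS,3,1,2.5,3
YOLOV5,4,4,4,4
YOLOV7,1,2,1,1
Ours,2,3,2.5,2
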