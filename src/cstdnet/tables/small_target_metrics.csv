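model,P,R,F1,AP
CenterNet,88.02,52.36,0.66,71.51
EfficientDet,95.55,22.0,0.36,39.77
SSD,89.45,47.42,0.57,57.28
FASSD,98.41,21.9,0.35,36.36
FCOS,84.80,63.56,0.73,74.69
RetinaNet,94.37,17.55,0.30,31.40
YOLOV5,84.47,51.22,0.63,63.45
YOLOV7,85.71,69.13,0.77,77.9
Ours,90.42,75.93,0.83,85.97
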