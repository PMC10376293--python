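model,P,R,F1,AP
CenterNet,88.62,53.70,0.67,72.83
EfficientDet,95.60,24.57,0.39,42.13
SSD,88.02,49.48,0.63,71.73
FASSD,92.41,31.17,0.46,48.52
FCOS,93.02,90.03,0.92,94.04
RetinaNet,94.69,19.85,0.33,33.79
YOLOV5,90.76,76.73,0.83,86.51
YOLOV7,95.13,89.47,0.94,95.72
Ours,94.52,88.75,0.92,94.59
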