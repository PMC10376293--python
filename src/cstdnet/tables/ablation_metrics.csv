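model,P,R,F1,AP
backbone,85.71,69.13,0.77,77.9
backbone+CIDM,88.78,73.17,0.8,81.42
backbone+FCM,88.84,74.22,0.82,83.63
backbone+CIDM+FCM,90.42,75.93,0.83,85.97
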