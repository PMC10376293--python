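model,P,R,F1,AP
backbone,4,4,4,4
backbone+CIDM,3,3,3,3
backbone+FCM,2,2,2,2
backbone+CIDM+FCM,1,1,1,1
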