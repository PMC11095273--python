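status,old_category,le10,gt10_le20,gt20_le40,gt40
event,le10,5,3,0,0
event,gt10_le20,5,55,14,1
event,gt20_le40,0,10,41,33
event,gt40,0,1,12,54
nonevent,le10,69,15,0,0
nonevent,gt10_le20,74,334,38,0
nonevent,gt20_le40,1,60,98,27
nonevent,gt40,0,0,29,39
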