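group,gw,hand,count
right,14,right,66
right,14,left,54
right,18,right,85
right,18,left,53
right,22,right,94
right,22,left,64
left,14,right,11
left,14,left,8
left,18,right,13
left,18,left,13
left,22,right,13
left,22,left,14
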