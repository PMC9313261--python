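subject,recording,posture,tp,fp,fn
A,r01,supine,282,3,1
A,r02,supine,281,0,0
A,r03,seated,280,1,0
A,r04,standing,260,15,7
B,r05,supine,267,4,1
B,r06,supine,284,8,2
B,r07,seated,274,0,0
B,r08,standing,275,17,2
C,r09,supine,275,2,2
C,r10,supine,271,3,2
C,r11,seated,273,4,1
C,r12,standing,269,14,0
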