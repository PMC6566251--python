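condition,parameter,threshold,value
1,q2,>0.5,0.734
2,r2,>0.6,0.966
3a,r02,close to r2,0.920
3b,r0_prime2,close to r2,0.944
4a,k,0.85<k<1.15,1.004
4b,k_prime,0.85<k'<1.15,0.995
5a,(r2-r02)/r2,<0.1,0.048
5b,(r2-r0'2)/r2,<0.1,0.023
6,|r02-r0'2|,<0.3,0.024
7,rm2,>0.5,0.723
8,qf1,>0.7,0.944
9,qf2,>0.7,0.943
10,qf3,>0.7,0.951
11,ccc,>0.85,0.967
12,delta_rm2,<0.2,0.056
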