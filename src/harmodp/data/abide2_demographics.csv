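site,scanner,tr_ms,te_ms,flip_angle,voxel_size,n_asd,n_hc,n_male,n_female,age_mean,age_sd
EMC,GE MR750,2000,30,85,3.6x3.6x4.0,14,13,22,5,8.39,1.03
ETH,Philips Achieva,2000,25,90,3x3x3,7,22,29,0,23.36,4.59
GU,Siemens TriTim,2000,30,90,3x3x3,27,41,46,22,10.89,1.62
IU,Siemens TriTim,813,28,60,3.4x3.4x3.4,18,19,28,9,24.62,7.59
KKI,Philips Achieva,2500,30,75,3x3x3,25,123,89,59,10.37,1.27
KUL,Philips Achieva,2500,30,90,1.6x1.6x3.1,25,0,25,0,23.76,5.10
OHSU,Siemens TriTim,475,30,60,3x3x3,33,51,52,32,11.00,2.04
ONRC,Siemens Skyra,2500,30,90,3.8x3.8x3.8,15,26,30,11,23.24,4.09
SU,GE SIGNA,2000,30,80,3.4x3.4x3.5,14,17,28,3,10.94,1.14
UCLA,Siemens TriTim,3000,28,90,3x3x4,12,12,19,5,11.04,2.46
USM,Siemens TriTim,2000,28,90,3.1x3.1x4,9,12,17,4,24.34,7.49
BNI,Philips Ingenia,3000,25,80,3.8x3.8x4,29,28,57,0,38.86,15.41
IP,Philips Achieva,2700,45,90,3.6x3.7x4,13,21,16,18,22.37,10.97
NYU,Siemens Allegra,2000,15,90,3x3x4,61,28,81,8,9.24,4.78
SDSU,GE MR750,2000,30,90,3.4x3.4x3.4,30,24,46,8,13.19,3.06
TCD,Philips Achieva,2000,27,90,3x3x3.2,9,17,26,0,15.98,3.23
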