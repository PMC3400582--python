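rnai,N2,isp-1;ctb-1,eat-2,daf-2
vector,18.1,27.0,26.2,38.7
phi-50,12.9,13.6,14.5,16.4
ima-3,16.9,18.5,18.1,22.2
wnk-1,16.5,19.6,18.2,24.4
elt-2,14.4,16.7,15.4,25.3
pas-3,16.8,19.3,19.5,30.2
cpf-2,17.1,21.6,19.1,30.9
let-70,17.2,19.1,18.2,32.2
mdt-26,15.7,22.5,19.6,29.4
cpsf-4,20.8,26.9,26.3,39.1
arf-3,18.1,20.8,22.7,34.5
gob-1,17.3,19.3,19.4,47.2
ufd-1,16.8,18.3,19.2,33.1
nekl-2,13.7,17.5,15.7,33.5
let-92,15.7,19.0,18.8,32.4
cul-1,18.0,24.9,22.1,40.8
C06A8.2,17.1,22.4,21.8,33.9
skr-1,19.1,23.4,25.1,38.1
sdc-2,15.5,18.6,20.7,35.7
Y50D7A.11,19.0,27.8,26.2,37.8
kin-1,13.3,17.1,18.4,36.4
dcp-66,12.7,13.5,17.5,34.2
hda-1,16.2,20.1,24.2,37.8
lin-40,17.3,23.1,25.6,38.7
dpy-22,17.6,24.6,25.9,41.9
F53F4.11,19.4,27.5,29.4,38.7
sptl-1,18.6,26.6,27.6,37.9
cpsf-2,18.9,30.0,29.4,39.6
F18F11.5,17.6,29.6,26.9,43.3
rab-10,18.3,28.6,26.1,39.6
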