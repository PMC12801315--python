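# enumerated C/H/N/O molecules, <= 10 heavy atoms
C
CC
CCC
CCCC
CCCCC
CCCCCC
CC(C)C
CC(C)(C)C
C=C
C=CC
CC=CC
C#C
C#CC
C=CC=C
C1CC1
C1CCC1
C1CCCC1
C1CCCCC1
C1CCCCCC1
C1CCOC1
C1CCOCC1
C1COCCO1
C1CCNC1
C1CCNCC1
C1COCCN1
C1CNCCN1
O=C1CCCC1
O=C1CCCCC1
O=C1CCC1
O=C1CCCCN1
O=C1CCCO1
O=C1CCCN1
c1ccccc1
Cc1ccccc1
CCc1ccccc1
Cc1ccccc1C
Cc1ccc(C)cc1
Oc1ccccc1
COc1ccccc1
Nc1ccccc1
CNc1ccccc1
Cc1ccc(O)cc1
O=Cc1ccccc1
CC(=O)c1ccccc1
OCc1ccccc1
NCc1ccccc1
Cc1ccc(N)cc1
C=Cc1ccccc1
N#Cc1ccccc1
O=C(O)c1ccccc1
c1ccncc1
Cc1ccncc1
Cc1cccnc1
Cc1ccccn1
c1cncnc1
c1ccoc1
Cc1ccco1
c1cc[nH]c1
Cc1ccc[nH]1
c1c[nH]cn1
O=Cc1ccco1
CC(=O)c1ccco1
Nc1ccncc1
Oc1ccncc1
OCC(O)CO
OCCO
OCCCO
NCCO
COCCO
NCCN
C=CCO
CC(C)O
CCC(C)O
CC(C)N
CC(O)C(C)O
CC(=O)CC(C)=O
C=CC(=O)OC
CC=CC=O
C=CC=O
C=CC(C)=O
CCOC(C)=O
O=CC=O
CC(=O)C(C)=O
C#CCO
N#CCN
O=C(O)CC(=O)O
CNC(C)=O
CN(C)C=O
CNC=O
NC(N)=O
CNC(N)=O
CN(C)C(N)=O
COCOC
COC(C)OC
C1COCO1
CC1CO1
C1CO1
CC1CCCO1
CO
CCO
CCCO
CCCCO
CC(C)CO
CCCCCO
COC
CCOC
CCCOC
CCCCOC
COCC(C)C
CCCCCOC
CN
CCN
CCCN
CCCCN
CC(C)CN
CCCCCN
CNC
CCNC
CCCNC
CCCCNC
CNCC(C)C
CCCCCNC
CC=O
CCC=O
CCCC=O
CCCCC=O
CC(C)CC=O
CCCCCC=O
CC(C)=O
CCC(C)=O
CCCC(C)=O
CCCCC(C)=O
CC(=O)CC(C)C
CCCCCC(C)=O
CC(=O)O
CCC(=O)O
CCCC(=O)O
CCCCC(=O)O
CC(C)CC(=O)O
CCCCCC(=O)O
COC(C)=O
CCC(=O)OC
CCCC(=O)OC
CCCCC(=O)OC
COC(=O)CC(C)C
CCCCCC(=O)OC
CC(N)=O
CCC(N)=O
CCCC(N)=O
CCCCC(N)=O
CC(C)CC(N)=O
CCCCCC(N)=O
CC#N
CCC#N
CCCC#N
CCCCC#N
CC(C)CC#N
CCCCCC#N
COC=O
CCOC=O
CCCOC=O
CCCCOC=O
CC(C)COC=O
CCCCCOC=O
CN(C)C
CCN(C)C
CCCN(C)C
CCCCN(C)C
CC(C)CN(C)C
CCCCCN(C)C
CC(C)CCO
CCCCCCO
CCCC(C)O
CCCCC(C)O
CC(C)CC(C)O
CCCCCC(C)O
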