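# Most abundant plasma proteins excluded from antigen candidate lists.
# Editable; one gene symbol per line.
ALB
TF
A2M
APOA1
APOA2
APOB
APOC3
C3
FGA
FGB
FGG
HP
SERPINA1
TTR
GC
AHSG
AMBP
APOH
ITIH1
ITIH2
ITIH4
SERPINC1
SERPING1
VTN
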