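# Acute-phase response proteins excluded from antigen candidate lists.
# Editable; one gene symbol per line.
CRP
SAA1
SAA2
SAA4
HP
HPX
FGA
FGB
FGG
SERPINA1
SERPINA3
ORM1
ORM2
C3
C4A
C4B
C9
CP
LBP
F2
PLG
TTR
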