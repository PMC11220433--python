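atc_code,label
H03AA01,Levothyroxine sodium
H03AA02,Liothyronine sodium
H03AA03,Combinations of levothyroxine and liothyronine
N02BE01,Paracetamol
M01AE01,Ibuprofen
N02BA01,Acetylsalicylic acid
N06AB10,Escitalopram
N06AB06,Sertraline
N06AX22,Agomelatine
M03BX01,Baclofen
N06AX21,Duloxetine
A10BX04,Exenatide
M05BX03,Strontium ranelate
M03BX07,Tetrazepam
L01CD01,Paclitaxel
L03AA13,Pegfilgrastim
L03AX13,Glatiramer acetate
B03AA07,Ferrous sulfate
L04AC10,Secukinumab
L01BA01,Methotrexate
A02BX05,Bismuth potassium
J01AA07,Tetracycline
P01AB01,Metronidazole
C07AB02,Metoprolol
C09AA05,Ramipril
C10AA01,Simvastatin
A02BC01,Omeprazole
A10BA02,Metformin
N05BA06,Lorazepam
N05CF01,Zopiclone
R06AE07,Cetirizine
R03AC02,Salbutamol
J01CA04,Amoxicillin
G03AA07,Levonorgestrel and ethinylestradiol
B01AC06,Acetylsalicylic acid low dose
N03AX16,Pregabalin
N02AA05,Oxycodone
A11CC05,Colecalciferol
A12AA04,Calcium carbonate
V03AB15,Naloxone
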