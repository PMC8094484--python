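res,ALA,ARG,ASN,ASP,CYS,GLN,GLU,GLY,HIS,ILE,LEU,LYS,MET,PHE,PRO,SER,THR,TRP,TYR,VAL
ALA,-3.80,-0.65,-1.15,-1.15,-4.15,-1.15,-1.15,-2.70,-1.30,-5.15,-4.80,-0.95,-3.85,-4.30,-2.10,-2.50,-2.55,-2.45,-2.25,-5.00
ARG,-0.65,2.50,2.00,2.00,-1.00,2.00,2.00,0.45,1.85,-2.00,-1.65,2.20,-0.70,-1.15,1.05,0.65,0.60,0.70,0.90,-1.85
ASN,-1.15,2.00,1.50,1.50,-1.50,1.50,1.50,-0.05,1.35,-2.50,-2.15,1.70,-1.20,-1.65,0.55,0.15,0.10,0.20,0.40,-2.35
ASP,-1.15,2.00,1.50,1.50,-1.50,1.50,1.50,-0.05,1.35,-2.50,-2.15,1.70,-1.20,-1.65,0.55,0.15,0.10,0.20,0.40,-2.35
CYS,-4.15,-1.00,-1.50,-1.50,-4.50,-1.50,-1.50,-3.05,-1.65,-5.50,-5.15,-1.30,-4.20,-4.65,-2.45,-2.85,-2.90,-2.80,-2.60,-5.35
GLN,-1.15,2.00,1.50,1.50,-1.50,1.50,1.50,-0.05,1.35,-2.50,-2.15,1.70,-1.20,-1.65,0.55,0.15,0.10,0.20,0.40,-2.35
GLU,-1.15,2.00,1.50,1.50,-1.50,1.50,1.50,-0.05,1.35,-2.50,-2.15,1.70,-1.20,-1.65,0.55,0.15,0.10,0.20,0.40,-2.35
GLY,-2.70,0.45,-0.05,-0.05,-3.05,-0.05,-0.05,-1.60,-0.20,-4.05,-3.70,0.15,-2.75,-3.20,-1.00,-1.40,-1.45,-1.35,-1.15,-3.90
HIS,-1.30,1.85,1.35,1.35,-1.65,1.35,1.35,-0.20,1.20,-2.65,-2.30,1.55,-1.35,-1.80,0.40,0.00,-0.05,0.05,0.25,-2.50
ILE,-5.15,-2.00,-2.50,-2.50,-5.50,-2.50,-2.50,-4.05,-2.65,-6.50,-6.15,-2.30,-5.20,-5.65,-3.45,-3.85,-3.90,-3.80,-3.60,-6.35
LEU,-4.80,-1.65,-2.15,-2.15,-5.15,-2.15,-2.15,-3.70,-2.30,-6.15,-5.80,-1.95,-4.85,-5.30,-3.10,-3.50,-3.55,-3.45,-3.25,-6.00
LYS,-0.95,2.20,1.70,1.70,-1.30,1.70,1.70,0.15,1.55,-2.30,-1.95,1.90,-1.00,-1.45,0.75,0.35,0.30,0.40,0.60,-2.15
MET,-3.85,-0.70,-1.20,-1.20,-4.20,-1.20,-1.20,-2.75,-1.35,-5.20,-4.85,-1.00,-3.90,-4.35,-2.15,-2.55,-2.60,-2.50,-2.30,-5.05
PHE,-4.30,-1.15,-1.65,-1.65,-4.65,-1.65,-1.65,-3.20,-1.80,-5.65,-5.30,-1.45,-4.35,-4.80,-2.60,-3.00,-3.05,-2.95,-2.75,-5.50
PRO,-2.10,1.05,0.55,0.55,-2.45,0.55,0.55,-1.00,0.40,-3.45,-3.10,0.75,-2.15,-2.60,-0.40,-0.80,-0.85,-0.75,-0.55,-3.30
SER,-2.50,0.65,0.15,0.15,-2.85,0.15,0.15,-1.40,0.00,-3.85,-3.50,0.35,-2.55,-3.00,-0.80,-1.20,-1.25,-1.15,-0.95,-3.70
THR,-2.55,0.60,0.10,0.10,-2.90,0.10,0.10,-1.45,-0.05,-3.90,-3.55,0.30,-2.60,-3.05,-0.85,-1.25,-1.30,-1.20,-1.00,-3.75
TRP,-2.45,0.70,0.20,0.20,-2.80,0.20,0.20,-1.35,0.05,-3.80,-3.45,0.40,-2.50,-2.95,-0.75,-1.15,-1.20,-1.10,-0.90,-3.65
TYR,-2.25,0.90,0.40,0.40,-2.60,0.40,0.40,-1.15,0.25,-3.60,-3.25,0.60,-2.30,-2.75,-0.55,-0.95,-1.00,-0.90,-0.70,-3.45
VAL,-5.00,-1.85,-2.35,-2.35,-5.35,-2.35,-2.35,-3.90,-2.50,-6.35,-6.00,-2.15,-5.05,-5.50,-3.30,-3.70,-3.75,-3.65,-3.45,-6.20
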