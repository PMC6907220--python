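compound_id,name,target_class,top_dose_nM,n_doses,dilution_factor
AZA,azacitidine,DNMT,10000,5,10
DEC,decitabine,DNMT,10000,5,10
GUA,guadecitabine,DNMT,10000,5,10
ZEB,zebularine,DNMT,10000,5,10
RG108,RG-108,DNMT,10000,5,10
SGI1027,SGI-1027,DNMT,10000,5,10
CM272,CM-272,DNMT,10000,5,10
VOR,vorinostat,HDAC,10000,5,10
PAN,panobinostat,HDAC,10000,5,10
BEL,belinostat,HDAC,10000,5,10
ENT,entinostat,HDAC,10000,5,10
ROM,romidepsin,HDAC,10000,5,10
MOC,mocetinostat,HDAC,10000,5,10
GIV,givinostat,HDAC,10000,5,10
PRA,pracinostat,HDAC,10000,5,10
QUI,quisinostat,HDAC,10000,5,10
ABX,abexinostat,HDAC,10000,5,10
DAC,dacinostat,HDAC,10000,5,10
RIC,ricolinostat,HDAC,10000,5,10
TBA,tubastatin-A,HDAC,10000,5,10
TUC,tucidinostat,HDAC,10000,5,10
VPA,valproic-acid,HDAC,10000,5,10
TAC,tacedinaline,HDAC,10000,5,10
DRX,droxinostat,HDAC,10000,5,10
RES,resminostat,HDAC,10000,5,10
CUDC101,CUDC-101,HDAC,10000,5,10
CIT,citarinostat,HDAC,10000,5,10
SCR,scriptaid,HDAC,10000,5,10
C646,C646,HAT,10000,5,10
TAZ,tazemetostat,HMT,10000,5,10
GSK126,GSK126,HMT,10000,5,10
EPZ5687,EPZ005687,HMT,10000,5,10
UNC1999,UNC1999,HMT,10000,5,10
GSK343,GSK343,HMT,10000,5,10
EPZ15666,EPZ015666,HMT,10000,5,10
LLY283,LLY-283,HMT,10000,5,10
EPZ4777,EPZ004777,HMT,10000,5,10
SGC0946,SGC0946,HMT,10000,5,10
A366,A-366,HMT,10000,5,10
UNC0638,UNC0638,HMT,10000,5,10
UNC0642,UNC0642,HMT,10000,5,10
BIX,BIX-01294,HMT,10000,5,10
AZ505,AZ505,HMT,10000,5,10
SGC707,SGC707,HMT,10000,5,10
GSKJ4,GSK-J4,HDM,10000,5,10
ORY,iadademstat,HDM,10000,5,10
TCP,tranylcypromine,HDM,10000,5,10
JQ1,JQ1,BRD,10000,5,10
IBET762,molibresib,BRD,10000,5,10
OTX015,birabresib,BRD,10000,5,10
CPI0610,pelabresib,BRD,10000,5,10
ABBV075,mivebresib,BRD,10000,5,10
IBET151,I-BET151,BRD,10000,5,10
PFI1,PFI-1,BRD,10000,5,10
BRSP,bromosporine,BRD,10000,5,10
RVX208,apabetalone,BRD,10000,5,10
DBET1,dBET1,BRD,10000,5,10
AZD5153,AZD5153,BRD,10000,5,10
BMS986158,BMS-986158,BRD,10000,5,10
PLX51107,PLX51107,BRD,10000,5,10
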