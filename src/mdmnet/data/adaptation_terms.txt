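# Default adaptation keyword list: gene families and processes repeatedly
# implicated in survival under extreme environmental stress (oxidative,
# thermal, osmotic, cold, radiation).  One case-insensitive substring per
# line; edit or replace freely.
rubrerythrin
ferritin
DPS
Fe-S oxidoreductase
OxyR
peroxide
peroxidase
peroxiredoxin
catalase
superoxide dismutase
oxidative stress
thioredoxin
glutaredoxin
rubredoxin
heat shock
chaperone
chaperonin
GroEL
GroES
DnaK
DnaJ
ClpB
cold shock
antifreeze
osmotic
osmoprotectant
compatible solute
glycine betaine
betaine
ectoine
trehalose
proline betaine
choline
halocin
bacteriorhodopsin
photolyase
DNA repair
RecA
RadA
UvrA
excinuclease
sigma factor
universal stress
stress response
starvation
spore
sporulation
toxin-antitoxin
efflux
multidrug resistance
arsenate reductase
mercuric reductase
nitric oxide reductase
carotenoid
exopolysaccharide
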