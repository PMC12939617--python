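verbatim	generic	is_combination	drug_class
prednisolone	prednisolone	0	glucocorticoid
prednisolone sodium phosphate	prednisolone	0	glucocorticoid
orapred	prednisolone	0	glucocorticoid
prelone	prednisolone	0	glucocorticoid
prednisolone acetate	prednisolone acetate	0	glucocorticoid
pred forte	prednisolone acetate	0	glucocorticoid
omnipred	prednisolone acetate	0	glucocorticoid
prednisone	prednisone	0	glucocorticoid
deltasone	prednisone	0	glucocorticoid
rayos	prednisone	0	glucocorticoid
triamcinolone acetonide	triamcinolone acetonide	0	glucocorticoid
kenalog	triamcinolone acetonide	0	glucocorticoid
triesence	triamcinolone acetonide	0	glucocorticoid
difluprednate	difluprednate	0	glucocorticoid
durezol	difluprednate	0	glucocorticoid
dexamethasone	dexamethasone	0	glucocorticoid
dexamethasone sodium phosphate	dexamethasone	0	glucocorticoid
decadron	dexamethasone	0	glucocorticoid
methylprednisolone	methylprednisolone	0	glucocorticoid
methylprednisolone sodium succinate	methylprednisolone	0	glucocorticoid
medrol	methylprednisolone	0	glucocorticoid
solu-medrol	methylprednisolone	0	glucocorticoid
hydrocortisone	hydrocortisone	0	glucocorticoid
hydrocortisone sodium succinate	hydrocortisone	0	glucocorticoid
cortef	hydrocortisone	0	glucocorticoid
budesonide	budesonide	0	glucocorticoid
pulmicort	budesonide	0	glucocorticoid
entocort	budesonide	0	glucocorticoid
fluticasone propionate	fluticasone propionate	0	glucocorticoid
flovent	fluticasone propionate	0	glucocorticoid
fluticasone furoate	fluticasone furoate	0	glucocorticoid
arnuity ellipta	fluticasone furoate	0	glucocorticoid
adalimumab	adalimumab	0	monoclonal antibody
humira	adalimumab	0	monoclonal antibody
infliximab	infliximab	0	monoclonal antibody
remicade	infliximab	0	monoclonal antibody
ranibizumab	ranibizumab	0	monoclonal antibody
lucentis	ranibizumab	0	monoclonal antibody
methotrexate	methotrexate	0	immunosuppressant
methotrexate sodium	methotrexate	0	immunosuppressant
trexall	methotrexate	0	immunosuppressant
mycophenolate mofetil	mycophenolate mofetil	0	immunosuppressant
cellcept	mycophenolate mofetil	0	immunosuppressant
ivacaftor	ivacaftor	0	cftr modulator
kalydeco	ivacaftor	0	cftr modulator
elexacaftor/ivacaftor/tezacaftor	elexacaftor/ivacaftor/tezacaftor	1	cftr modulator
elexacaftor / ivacaftor / tezacaftor	elexacaftor/ivacaftor/tezacaftor	1	cftr modulator
trikafta	elexacaftor/ivacaftor/tezacaftor	1	cftr modulator
kaftrio	elexacaftor/ivacaftor/tezacaftor	1	cftr modulator
ivacaftor/lumacaftor	ivacaftor/lumacaftor	1	cftr modulator
lumacaftor/ivacaftor	ivacaftor/lumacaftor	1	cftr modulator
orkambi	ivacaftor/lumacaftor	1	cftr modulator
melphalan	melphalan	0	antineoplastic
melphalan hydrochloride	melphalan	0	antineoplastic
alkeran	melphalan	0	antineoplastic
topotecan	topotecan	0	antineoplastic
topotecan hydrochloride	topotecan	0	antineoplastic
hycamtin	topotecan	0	antineoplastic
cisplatin	cisplatin	0	antineoplastic
platinol	cisplatin	0	antineoplastic
topiramate	topiramate	0	antiepileptic
topamax	topiramate	0	antiepileptic
filgrastim	filgrastim	0	colony-stimulating factor
neupogen	filgrastim	0	colony-stimulating factor
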