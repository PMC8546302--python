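# Trait registry: code, full name, category (agronomic / quality / micronutrient).
# Category assignment is this package's own (micronutrient = grain/shoot mineral
# content and efficiency codes; quality = protein, rheology, sedimentation,
# hardness, density; all remaining codes agronomic).
code	name	category
200KW	200-kernel weight	agronomic
25%G	25% green leaf area	agronomic
50%G	50% green leaf area	agronomic
75%G	75% green leaf area	agronomic
AGB	Above ground biomass	agronomic
BDT	Break down time	quality
BM	Biomass	agronomic
BY	Biological yield	agronomic
CDMA	Culm dry matter accumulation	agronomic
CID	Carbon isotope discrimination	agronomic
DA	Days to anthesis	agronomic
DDT	Dough development time	quality
DGC	Dry gluten content	quality
DH	Days to heading	agronomic
DPM	Days to physiological maturity	agronomic
DST	Dough stability time	quality
DTF	Days to flowering	agronomic
FFD	Factor form density	quality
FLH	Flag leaf height	agronomic
FWA	Flour water absorption	quality
GAS	Grain area size	agronomic
GCuC	Grain Cu content	micronutrient
GFD	Grain filling duration	agronomic
GFeC	Grain Fe content	micronutrient
GFR	Grain filling rate	agronomic
GL	Grain length	agronomic
GL/GW	Grain length/grain width ratio	agronomic
GMnC	Grain Mn content	micronutrient
GN	Grain number	agronomic
GPC	Grain protein content	quality
GPL	Grain perimeter length	agronomic
GSeC	Grain Se content	micronutrient
GW	Grain width	agronomic
GWe	Grain weight/ear	agronomic
GWs	Grain weight/spike	agronomic
GY	Grain yield	agronomic
GZnC	Grain Zn content	micronutrient
HI	Harvest index	agronomic
HW	Hectoliter weight	quality
KH	Kernel hardness	quality
KL	Kernel length	agronomic
KW	Kernel width	agronomic
LDMA	Leaves dry matter accumulation	agronomic
LL	Leaf length	agronomic
LS	Lodging score	agronomic
LW	Leaf width	agronomic
LY	Leaf yellowing	agronomic
MDR	Maturity date	agronomic
MRS	Maximum rate of senescence	agronomic
MTI	Mixing tolerance index	quality
NG	Number of grain per spike	agronomic
PDMA	Plants dry matter accumulation	agronomic
PGMS	Percent green at maximum senescence	agronomic
PH	Plant height	agronomic
PLH	Penultimate leaf height	agronomic
PT	Productive tillers/m2	agronomic
SD	Seed diameter	agronomic
SDS	Sedimentation rate	quality
SHS	Shattering score	agronomic
SHZnC	Shoot Zn content	micronutrient
SL	Spike length	agronomic
SN	Spike number	agronomic
SNS	Spikelet number per spike	agronomic
SW	Spike weight	agronomic
TKW	Thousand kernel weight	agronomic
TMRS	Time to maximum rate of senescence	agronomic
TN	Tiller number/m2	agronomic
UIH	Uppermost internode height	agronomic
WGC	Wet gluten content	quality
ZnE	Zn efficiency	micronutrient
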