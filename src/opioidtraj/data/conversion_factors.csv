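ingredient,route,factor,strength_unit,patch_wear_days
codeine,oral,0.15,mg,
dihydrocodeine,oral,0.25,mg,
meptazinol,oral,0.1,mg,
tramadol,oral,0.1,mg,
tapentadol,oral,0.4,mg,
morphine,oral,1.0,mg,
oxycodone,oral,1.5,mg,
hydromorphone,oral,4.0,mg,
diamorphine,oral,1.5,mg,
pethidine,oral,0.1,mg,
buprenorphine,oral,10.0,mg,
methadone,oral,4.0,mg,
fentanyl,transdermal,2.4,ug_per_hour,3
buprenorphine,transdermal,12.6,ug_per_hour,7
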