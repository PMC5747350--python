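metabolite,mass,mass_type
mevalonate,148.073559,neutral
alpha-ketoglutarate,146.021523,neutral
cholesterol,386.354866,neutral
cholesterol-sulfate,466.311723,neutral
HMG-CoA,911.124122,neutral
T0901317,480.031699,ion
GW3965,580.18633,ion
hydroxy-GW3965,596.181546,ion
hydroxy-atorvastatin,573.240091,ion
atorvastatin-lactone,539.234611,ion
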