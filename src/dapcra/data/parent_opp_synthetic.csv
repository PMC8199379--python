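# Synthetic parent-OPP parameter table (editable placeholder).
# Molecular weights are the real parent-pesticide values (g/mol);
# BMDL10 values (ug/kg/day, rat brain-ChE inhibition endpoint) and
# annual release amounts (tonnes/year) are plausible placeholders for
# an appendix table not available here.  Replace with authoritative
# values before any substantive use.
name,alkyl_class,molecular_weight,bmdl10,release_2011,release_2012,release_2013,release_2014
fenitrothion,dimethyl,277.23,13.0,600,590,580,570
methidathion,dimethyl,302.33,2.2,60,58,56,54
malathion,dimethyl,330.36,500.0,80,78,76,74
trichlorfon,dimethyl,257.44,50.0,40,39,38,37
dimethoate,dimethyl,229.26,25.0,30,29,28,27
pirimiphos-methyl,dimethyl,305.33,70.0,10,10,9,9
diazinon,diethyl,304.35,52.0,120,115,110,105
chlorpyrifos,diethyl,350.59,76.0,40,38,36,34
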