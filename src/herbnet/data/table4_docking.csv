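target,pdb_id,compound,affinity_kcal_mol
BIRC5,3UEG,luteolin,-8.2
BIRC5,3UEG,quercetin,-7.7
CCNA2,1H1P,8-Isopentenyl-kaempferol,-7.8
CCNA2,1H1P,formononetin,-7.3
CCNA2,1H1P,Glyceollin,-8.2
CCNA2,1H1P,Phaseolin,-8.2
CCNA2,1H1P,Wighteone,-7.5
CDK1,6GU7,quercetin,-7.4
PRKCB,2I0E,quercetin,-7.5
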