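# 12-dam breeding-trial fixture; delivering counts reconstructed from printed group percentages
dam_id,group,month,pups_born,pups_weaned
ctl_1,control,1,14,13
ctl_1,control,2,13,13
ctl_1,control,3,14,12
ctl_2,control,1,14,13
ctl_2,control,2,13,13
ctl_2,control,3,14,12
ctl_3,control,1,14,13
ctl_3,control,2,13,13
ctl_3,control,3,14,12
ctl_4,control,1,14,13
ctl_4,control,2,13,13
ctl_4,control,3,14,12
ctl_5,control,1,14,13
ctl_5,control,2,13,13
ctl_5,control,3,14,12
ctl_6,control,1,14,13
ctl_6,control,2,13,13
ctl_6,control,3,14,12
adm_1,adenomyosis,2,7,6
adm_2,adenomyosis,2,7,7
adm_3,adenomyosis,,,
adm_4,adenomyosis,,,
adm_5,adenomyosis,,,
adm_6,adenomyosis,,,
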