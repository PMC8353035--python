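study_label,measure,n,mean,dispersion_kind,dispersion_value,ci_lower,ci_upper,ci_level
Nguyen 2013,TOJ,19,25.1,SE,3.18887870,,,
Jones 2016,TOJ,16,48.8,SE,3.80000000,,,
Tommerdahl 2016,TOJ,58,36.4,SE,2.79682702,,,
Pearce 2019,TOJ,20,23.8,SD,10.10000000,,,
Nguyen 2013,TOJc,19,84.7,SE,13.39787886,,,
Tommerdahl 2016,TOJc,58,95.2,SE,4.29372035,,,
Nguyen 2013,DUR,23,65.0,SE,6.90182711,,,
Tommerdahl 2016,DUR,58,64.6,SE,3.70284141,,,
Pearce 2019,DUR,20,48.7,SD,19.10000000,,,
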