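# Small demonstration cohort: 5 patient-like + 5 control-like subjects
# (the study-scale default is 17/18; recordings stay at the 300 s default).
n_ad: 5
n_hc: 5
n_boot: 2000
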