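direction,fisher_statistic,p_value
co2->migr,107.156,0.000
migr->co2,104.003,0.000
hexp->migr,90.565,0.001
migr->hexp,92.942,0.001
hexp->co2,115.396,0.000
co2->hexp,117.682,0.000
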