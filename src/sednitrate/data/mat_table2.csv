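# Diatom-mat summary fixture (April mat sample): replicate means with
# standard deviations, concentrations per dm3 of mat.
statistic,icno3_umol_dm3,fucoxanthin_umol_dm3,chlorophyll_a_umol_dm3,cells_dm3
mean,65.1,27.8,16.8,1.40e10
sd,9.8,8.0,4.0,1.38e9
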