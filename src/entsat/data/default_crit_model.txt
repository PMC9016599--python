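# entsat critical-value model
statistic = t_inf
positives = topology
intercept = 2.2208403770383
coef_sqrt_taxa = 3.1184532164753036
coef_sqrt_len = -0.04860929659091762
adjusted_r2 = 0.6912065465335949
taxa_min = 8.0
taxa_max = 128.0
len_min = 375.0
len_max = 1125.0
# bin: n_taxa length_mid t_crit tpr fpr n
bin = 8 375 5.0789017215868766 0.62962962962962965 0.11594202898550725 96
bin = 8 625 6.8833538844926156 0.59999999999999998 0.070707070707070704 114
bin = 8 875 4.2580394805716919 0.2857142857142857 0.013333333333333334 89
bin = 8 1125 4.3313992938577552 0 0 100
bin = 32 375 24.536447488137 1 0.66666666666666663 93
bin = 32 625 27.345089720190096 0.96969696969696972 0.59259259259259256 93
bin = 32 875 31.646368341184136 0.94444444444444442 0.63157894736842102 110
bin = 32 1125 18.275316075070045 0.65384615384615385 0.28888888888888886 97
bin = 128 375 35.700157352822345 0.98734177215189878 0.80000000000000004 89
bin = 128 625 25.84749544121301 0.97468354430379744 0.66666666666666663 94
bin = 128 875 39.235297934037163 0.95238095238095233 0.78787878787878785 117
bin = 128 1125 34.806606946235263 0.92592592592592593 0.55555555555555558 108
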