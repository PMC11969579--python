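group,strategy,ly,qaly,cost,icur
annual_40_75,usual_care,19.6901,17.3186,6908,
annual_40_75,high_risk_f2f,19.6929,17.3454,17174,412528
annual_40_75,high_risk_ai,19.6929,17.3461,18171,455855
annual_40_75,universal_f2f,19.6963,17.3663,22103,338099
annual_40_75,universal_ai,19.6963,17.3670,23959,374287
annual_50_75,usual_care,15.6041,14.1445,5061,
annual_50_75,high_risk_f2f,15.6047,14.1727,11007,413619
annual_50_75,high_risk_ai,15.6047,14.1732,11964,473598
annual_50_75,universal_f2f,15.6068,14.1906,17176,385918
annual_50_75,universal_ai,15.6067,14.1911,18716,434713
quinquennial_40_75,usual_care,19.6901,17.3189,6908,
quinquennial_40_75,high_risk_f2f,19.6910,17.3037,9621,432630
quinquennial_40_75,high_risk_ai,19.6911,17.3261,10150,507474
quinquennial_40_75,universal_f2f,19.6922,17.3328,11225,344697
quinquennial_40_75,universal_ai,19.6923,17.3332,11897,393870
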