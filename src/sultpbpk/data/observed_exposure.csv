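population,dose_mg_per_kg,parameter,observed,obs_low,obs_high,statistic,source
adult,5,cmax,4.74,,,mean,Clements 1984 (IV infusion 2 h)
adult,5,auc,18.4,16.75,20.05,mean_sd,Clements 1984 (IV infusion 2 h)
adult,20,cmax,17.8,,,mean,Clements 1984 (IV infusion 2 h)
adult,20,auc,82.5,72.5,92.5,mean_sd,Clements 1984 (IV infusion 2 h)
child,12.5,cmax,24.3,3.8,35.1,median_range,Zuppa 2011 (12.5 mg/kg Q6h)
child,12.5,auc,37.8,11.3,52.3,median_range,Zuppa 2011 (12.5 mg/kg Q6h)
infant,12.5,cmax,21.9,4.2,25.3,median_range,Zuppa 2011 (12.5 mg/kg Q4h)
infant,12.5,auc,43.3,9.2,79.2,median_range,Zuppa 2011 (12.5 mg/kg Q4h)
neonate,12.5,cmax,19.9,19.3,20.5,median_range,Zuppa 2011 (12.5 mg/kg Q4h)
neonate,12.5,auc,65.6,55.8,75.4,median_range,Zuppa 2011 (12.5 mg/kg Q4h)
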