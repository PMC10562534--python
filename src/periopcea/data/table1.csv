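name,base,low,high,psa_class,units
body_weight_kg,70,52.5,87.5,normal,kg
bsa_m2,1.86,1.40,2.33,normal,m2
discount_rate,0.03,0,0.08,uniform,rate/yr
p_surgery_mortality_30d,0.023,0.017,0.029,beta,probability
proportion_surgery_or_rt_pembrolizumab,0.821,0.61575,1.0,beta,probability
proportion_surgery_or_rt_placebo,0.794,0.5955,0.9925,beta,probability
proportion_adjuvant_uptake,0.892,0.669,1.0,beta,probability
nonsquamous_fraction,0.568,0.426,0.71,beta,probability
fraction_radiotherapy,0.1,0.075,0.125,beta,probability
price_pembrolizumab_mg,54.81,41.11,68.51,gamma,USD/mg
price_cisplatin_mg,0.32,0.24,0.40,gamma,USD/mg
price_pemetrexed_mg,6.45,4.84,8.06,gamma,USD/mg
price_gemcitabine_mg,0.02,0.01,0.03,gamma,USD/mg
cost_radiotherapy,16335.11,12251.33,20418.89,gamma,USD
cost_surgery,15687.42,11765.57,19609.28,gamma,USD
infusion_first_hour,132.16,99.12,165.2,gamma,USD
infusion_additional_hour,28.47,21.35,35.59,gamma,USD
infusion_subsequent_hour,65.06,48.80,81.33,gamma,USD
cost_best_supportive_care,3674.65,2755.99,4593.31,gamma,USD
cost_end_of_life,17909.24,13431.93,22386.55,gamma,USD
cost_follow_up,545.92,409.44,682.40,gamma,USD
sae_cost_anemia,2024.32,1518.24,2530.40,gamma,USD
sae_cost_neutropenia,1276.52,957.39,1595.65,gamma,USD
sae_cost_thrombocytopenia,2220.14,1665.11,2775.18,gamma,USD
utility_radiotherapy,0.79,0.71,0.87,beta,utility
utility_surgery,0.73,0.66,0.80,beta,utility
utility_PD,0.65,0.59,0.72,beta,utility
utility_PF,0.75,0.68,0.83,beta,utility
disutility_anemia,0.25,0.23,0.28,beta,disutility
disutility_neutropenia,0.07,0.06,0.08,beta,disutility
disutility_thrombocytopenia,0.35,0.32,0.39,beta,disutility
sae_risk_anemia_pembrolizumab,0.07,0.05,0.09,beta,probability
sae_risk_neutropenia_pembrolizumab,0.21,0.16,0.26,beta,probability
sae_risk_thrombocytopenia_pembrolizumab,0.05,0.04,0.06,beta,probability
sae_risk_anemia_placebo,0.06,0.05,0.08,beta,probability
sae_risk_neutropenia_placebo,0.20,0.15,0.25,beta,probability
sae_risk_thrombocytopenia_placebo,0.06,0.05,0.08,beta,probability
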