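trial_id,indication_id,drug,cancer_type,year_approved,setting,endpoint,hr,ci_lower,ci_upper,ci_level,median_control,median_experimental,landmark_survival,toxicity_points_override,tail_bonus_override,qol,toxicity_reduced,palliation_improved,tfi_improved,toxic_death_increased,long_term_benefit_reported,assessment_phase,expected_treatment_effect,expected_toxicity,expected_tail,expected_palliation,expected_qol,expected_tfi,expected_nhb,expected_esmo_grade
PACIFIC,PACIFIC,Durvalumab,NSCLC,2018,non_curative,OS,0.68,0.47,0.997,99.73,,,,-6.2,16,not_reported,False,False,False,False,False,updated,32,-6.2,16,0,0,0,41.8,4
OAK,OAK,Atezolizumab,NSCLC,2016,non_curative,OS,0.75,0.64,0.89,95.0,,,,2.7,0,not_improved,True,True,False,False,False,updated,25,2.7,0,10,0,0,37.7,5
KEYNOTE-45,KEYNOTE-45,Pembrolizumab,Urothelial carcinoma,2017,non_curative,OS,0.73,0.59,0.91,95.0,,,,1.0,20,improved,True,True,False,False,False,updated,27,1.0,20,10,10,0,68.0,4
KEYNOTE-24,KEYNOTE-24,Pembrolizumab,NSCLC,2017,non_curative,OS,0.6,0.41,0.89,95.0,,,,5.9,0,improved,True,True,False,False,False,updated,40,5.9,0,10,10,0,65.9,5
KEYNOTE-006-1,KEYNOTE-006,Pembrolizumab,Melanoma,2015,non_curative,OS,0.68,0.53,0.87,95.0,,,,2.3,16,improved,False,False,False,False,False,updated,32,2.3,16,0,10,0,60.3,5
KEYNOTE-006-2,KEYNOTE-006,Pembrolizumab,Melanoma,2015,non_curative,OS,0.68,0.53,0.86,95.0,,,,3.1,16,improved,False,False,False,False,False,updated,32,3.1,16,0,10,0,61.1,5
CHECKMATE-141,CHECKMATE-141,Nivolumab,SCCHN,2016,non_curative,OS,0.68,0.54,0.86,95.0,5.1,7.5,"[[24.0, 0.06, 0.169]]",7.1,20,improved,True,True,False,False,False,updated,32,7.1,20,10,10,0,79.1,5
CHECKMATE-025,CHECKMATE-025,Nivolumab,RCC,2015,non_curative,OS,0.73,0.57,0.93,98.5,,,,6.8,0,improved,True,True,False,False,False,updated,27,6.8,0,10,10,0,53.8,5
CHECKMATE-017,CHECKMATE-017,Nivolumab,NSCLC,2015,non_curative,OS,0.62,0.48,0.8,95.0,,,,11.3,20,improved,True,True,False,False,False,updated,38,11.3,20,10,10,0,89.3,5
CHECKMATE-057,CHECKMATE-057,Nivolumab,NSCLC,2015,non_curative,OS,0.73,0.62,0.88,95.0,,,,8.3,20,improved,True,True,False,False,False,updated,27,8.3,20,10,10,0,75.3,5
CHECKMATE-066,CHECKMATE-066,Nivolumab,Melanoma,2015,non_curative,OS,0.42,0.25,0.73,99.79,,,,2.4,16,improved,False,False,False,False,False,updated,58,2.4,16,0,10,0,86.4,5
CHECKMATE-067-1,CHECKMATE-067,Nivolumab plus ipilimumab,Melanoma,2015,non_curative,OS,0.54,0.44,0.67,95.0,,,,-9.0,20,not_improved,False,False,True,True,False,updated,46,-9.0,20,0,0,10,67.0,3
CHECKMATE-067-2,CHECKMATE-067,Nivolumab,Melanoma,2015,non_curative,OS,0.65,0.53,0.79,95.0,,,,0.3,20,not_improved,False,False,False,False,False,updated,35,0.3,20,0,0,0,55.3,4
KEYNOTE-002-1,KEYNOTE-002,Pembrolizumab,Melanoma,2015,non_curative,PFS,0.57,0.45,0.73,95.0,,,,5.4,16,improved,True,True,False,False,True,updated,34.4,5.4,16,10,10,0,75.8,4
KEYNOTE-002-2,KEYNOTE-002,Pembrolizumab,Melanoma,2015,non_curative,PFS,0.5,0.39,0.64,95.0,,,,4.4,16,improved,True,True,False,False,True,updated,40,4.4,16,10,10,0,80.4,4
EORTC-18071,EORTC-18071,Ipilimumab,Melanoma,2015,curative,OS,0.72,0.58,0.88,95.0,,,,-8.5,0,not_improved,False,False,False,False,False,updated,28,-8.5,0,0,0,0,19.5,A
MDX010-20-1,MDX010-20,Ipilimumab,Melanoma,2011,non_curative,OS,0.66,0.51,0.87,95.0,,,,1.0,20,not_improved,False,False,False,False,False,updated,34,1.0,20,0,0,0,55.0,4
MDX010-20-2,MDX010-20,Ipilimumab plus gp100,Melanoma,2011,non_curative,OS,0.68,0.55,0.85,95.0,,,,-0.3,20,not_improved,False,False,False,False,False,updated,32,-0.3,20,0,0,0,51.7,4
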