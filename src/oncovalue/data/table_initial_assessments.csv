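trial_id,indication_id,drug,cancer_type,year_approved,setting,endpoint,hr,ci_lower,ci_upper,ci_level,median_control,median_experimental,landmark_survival,toxicity_points_override,tail_bonus_override,qol,toxicity_reduced,palliation_improved,tfi_improved,toxic_death_increased,long_term_benefit_reported,assessment_phase,expected_treatment_effect,expected_toxicity,expected_tail,expected_palliation,expected_qol,expected_tfi,expected_nhb,expected_esmo_grade
KEYNOTE-189,KEYNOTE-189,Pembrolizumab plus chemotherapy,NSCLC,2018,non_curative,OS,0.49,0.38,0.64,95.0,,,,-7.5,16,not_reported,False,False,False,False,False,initial,51,-7.5,16,0,0,0,59.5,4
CHECKMATE-214,CHECKMATE-214,Nivolumab plus ipilimumab,RCC,2018,non_curative,OS,0.63,0.44,0.89,99.8,,,,4.9,0,improved,True,False,False,False,False,initial,37,4.9,0,0,10,0,51.9,5
PACIFIC,PACIFIC,Durvalumab,NSCLC,2018,non_curative,PFS,0.52,0.42,0.65,95.0,,,,-6.7,16,not_reported,False,False,False,False,True,initial,38.4,-6.7,16,0,0,0,47.7,4
OAK,OAK,Atezolizumab,NSCLC,2016,non_curative,OS,0.73,0.62,0.87,95.0,,,,2.7,0,not_reported,True,False,False,False,False,initial,27,2.7,0,0,0,0,29.7,5
KEYNOTE-45,KEYNOTE-45,Pembrolizumab,Urothelial carcinoma,2017,non_curative,OS,0.73,0.59,0.91,95.0,,,,1.0,20,not_reported,True,False,False,False,False,initial,27,1.0,20,0,0,0,48.0,4
KEYNOTE-24,KEYNOTE-24,Pembrolizumab,NSCLC,2017,non_curative,OS,0.6,0.41,0.89,95.0,,,,5.9,0,not_reported,True,False,False,False,False,initial,40,5.9,0,0,0,0,45.9,5
KEYNOTE-010-1,KEYNOTE-010,Pembrolizumab,NSCLC,2016,non_curative,OS,0.61,0.49,0.75,95.0,,,,5.7,20,not_reported,True,False,False,False,False,initial,39,5.7,20,0,0,0,64.7,5
KEYNOTE-010-2,KEYNOTE-010,Pembrolizumab,NSCLC,2016,non_curative,OS,0.71,0.58,0.88,95.0,,,,6.6,20,not_reported,True,False,False,False,False,initial,29,6.6,20,0,0,0,55.6,3
KEYNOTE-006-1,KEYNOTE-006,Pembrolizumab,Melanoma,2015,non_curative,OS,0.69,0.52,0.9,95.0,,,,2.3,16,not_reported,True,False,False,False,False,initial,31,2.3,16,0,0,0,49.3,5
KEYNOTE-006-2,KEYNOTE-006,Pembrolizumab,Melanoma,2015,non_curative,OS,0.63,0.47,0.83,95.0,,,,3.1,16,not_reported,True,False,False,False,False,initial,37,3.1,16,0,0,0,56.1,5
CHECKMATE-238,CHECKMATE-238,Nivolumab,Melanoma,2017,curative,RFS_DFS,0.65,0.51,0.83,95.0,,,,3.8,0,not_improved,True,False,False,False,False,initial,35,3.8,0,0,0,0,38.8,A
CHECKMATE-141,CHECKMATE-141,Nivolumab,SCCHN,2016,non_curative,OS,0.7,0.52,0.92,95.0,5.1,7.5,,7.1,20,improved,True,True,False,False,False,initial,30,7.1,20,10,10,0,77.1,4
CHECKMATE-025,CHECKMATE-025,Nivolumab,RCC,2015,non_curative,OS,0.73,0.57,0.93,98.5,,,,6.8,0,improved,True,False,False,False,False,initial,27,6.8,0,0,10,0,43.8,5
CHECKMATE-017,CHECKMATE-017,Nivolumab,NSCLC,2015,non_curative,OS,0.59,0.44,0.79,95.0,,,,11.3,20,not_reported,True,False,False,False,False,initial,41,11.3,20,0,0,0,72.3,5
CHECKMATE-057,CHECKMATE-057,Nivolumab,NSCLC,2015,non_curative,OS,0.73,0.6,0.89,95.0,,,,8.3,20,not_reported,True,False,False,False,False,initial,27,8.3,20,0,0,0,55.3,5
CHECKMATE-066,CHECKMATE-066,Nivolumab,Melanoma,2015,non_curative,OS,0.42,0.25,0.73,99.79,,,,2.4,16,not_improved,False,False,False,False,False,initial,58,2.4,16,0,0,0,76.4,4
CHECKMATE-067-1,CHECKMATE-067,Nivolumab plus ipilimumab,Melanoma,2015,non_curative,PFS,0.42,0.31,0.57,99.5,,,,-5.1,16,not_reported,False,False,False,True,True,initial,46.4,-5.1,16,0,0,0,57.3,3
CHECKMATE-067-2,CHECKMATE-067,Nivolumab,Melanoma,2015,non_curative,PFS,0.57,0.43,0.76,99.5,,,,5.5,16,not_reported,True,False,False,False,True,initial,34.4,5.5,16,0,0,0,55.9,4
KEYNOTE-002-1,KEYNOTE-002,Pembrolizumab,Melanoma,2015,non_curative,PFS,0.57,0.45,0.73,95.0,,,,7.3,16,not_reported,True,False,False,False,True,initial,34.4,7.3,16,0,0,0,57.7,4
KEYNOTE-002-2,KEYNOTE-002,Pembrolizumab,Melanoma,2015,non_curative,PFS,0.5,0.39,0.64,95.0,,,,5.9,16,not_reported,True,False,False,False,True,initial,40,5.9,16,0,0,0,61.9,4
EORTC-18071,EORTC-18071,Ipilimumab,Melanoma,2015,curative,RFS_DFS,0.75,0.64,0.9,95.0,,,,-7.6,0,not_improved,False,False,False,False,False,initial,25,-7.6,0,0,0,0,17.4,A
MDX010-20-1,MDX010-20,Ipilimumab,Melanoma,2011,non_curative,OS,0.66,0.51,0.87,95.0,,,,1.0,20,not_reported,False,False,False,False,False,initial,34,1.0,20,0,0,0,55.0,4
MDX010-20-2,MDX010-20,Ipilimumab plus gp100,Melanoma,2011,non_curative,OS,0.68,0.55,0.85,95.0,,,,-0.34,20,not_reported,False,False,False,False,False,initial,32,-0.34,20,0,0,0,51.7,4
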