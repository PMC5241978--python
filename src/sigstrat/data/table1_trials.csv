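trial_id,diagnosis,has_specific_symptoms,has_patient_specific_variables,outcome_granularity,outcome_linked_to_patient_variables,evidence_c2,evidence_c3,evidence_c4,evidence_c5,score,note
NCT00548327,Scz/SczAff,false,true,domain_specific_with_change,true,reported,reported,reported,reported,4,"No symptoms beyond diagnosis; COMT allele and plasma level as patient-specific variables; imaging signal change analysed by genotype."
NCT00560937,Scz/SczAff,true,false,composite_only,false,reported,reported,reported,reported,2,"Cognitive-testing score threshold as specific feature; outcomes all total/mean/composite."
NCT00611806,Scz,true,true,domain_specific_with_change,true,reported,reported,reported,reported,5,"Negative and positive symptoms plus genotype and plasma levels; domain-level outcomes with change, analysed by genotype."
NCT00931996,Scz,false,false,composite_only,false,reported,reported,reported,reported,1,"Threshold on an aggregate total only — not judged a specific-symptom criterion; single composite outcome."
NCT00963924,Scz/SczAff,true,true,composite_only,true,reported,reported,reported,reported,4,"Auditory discrimination plus negative-symptom score; primary outcome composite only, secondary subscores analysed per subject."
NCT00488319,Scz,false,false,domain_specific_with_change,false,reported,reported,reported,reported,2,"No specific symptoms or response factors; factor/domain scores with change reported."
NCT01312272,Scz,false,false,domain_specific_with_change,false,reported,reported,reported,reported,2,"Domain-level social-cognition outcomes with change; no stratifying variables."
NCT00922272,Scz,true,false,domain_specific_with_change,false,reported,reported,reported,reported,3,"Negative symptoms as specific feature; domain scores with change."
NCT00487942,Scz,false,true,domain_specific_with_change,false,reported,reported,reported,reported,3,"Named antipsychotic as patient-specific factor; domain scores with change."
NCT01363349,Scz,true,false,composite_only,false,reported,reported,reported,reported,2,"Specific psychotic symptoms listed; stable-antipsychotic inclusion not judged a response factor; composite primary outcome."
NCT00575666,Scz/SczAff,false,false,domain_specific_with_change,false,reported,reported,reported,reported,2,"Cognition reported as domain scores with change; no stratifying variables."
NCT00848484,Scz,false,true,composite_only,false,reported,reported,reported,reported,2,"Illness duration under one year as patient-specific factor; primary outcomes composite."
NCT00435370,Scz/schizophreniform,true,true,composite_only,true,reported,reported,reported,reported,4,"Psychotic features plus EEG P50 biomarker; primary outcome composite, secondary domain scores analysed per subject."
NCT01082588,Scz/SczAff,false,false,domain_specific_with_change,false,reported,reported,reported,reported,2,"Domain scores with change among secondary outcomes; no stratifying variables."
NCT00563706,Scz,true,false,composite_only,false,reported,reported,reported,reported,2,"Acute exacerbation as qualitative specific feature; domain-level secondaries unreported, composite primary."
NCT00506077,Scz,true,true,domain_specific_with_change,false,reported,reported,reported,reported,4,"Symptom-range threshold and baseline-matched cognition; domain scores with change; linkage only partial, not counted."
NCT00646581,Scz/SczAff,false,false,domain_specific_with_change,false,reported,reported,reported,reported,2,"Stable-antipsychotic inclusion not judged a response factor; cognition as domain scores with change."
NCT00455702,Scz/SczAff,true,false,domain_specific_with_change,true,reported,reported,reported,reported,4,"Depressed-subtype feature; domain scores with change; outcomes analysed against demographics."
NCT00505076,Scz,true,false,composite_only,false,reported,reported,reported,reported,2,"Low positive-symptom and low cognition thresholds; composite/total outcomes only."
NCT00000371,Scz,true,true,composite_only,true,reported,reported,reported,reported,4,"Prominent negative symptoms plus serum concentrations; primary outcome total score, secondary domain scores correlated with serum levels."
NCT00333970,Scz spectrum,true,true,composite_only,false,reported,insufficient,reported,reported,2,"Neuropsychological baseline feature; demographics/illness variables flagged but not specified — insufficient evidence demotes criterion 3."
NCT01315002,Scz,false,true,composite_only,false,reported,reported,reported,reported,2,"Smoking status, relatives and cholinergic polymorphisms as patient-specific variables; single task-error outcome."
NCT01207219,Scz/SczAff spectrum,false,false,domain_specific_with_change,false,reported,reported,insufficient,reported,0,"Domain scores listed but change results unreported — insufficient evidence demotes criterion 4 to none."
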