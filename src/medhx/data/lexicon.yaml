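# Default disease lexicon: canonical disease name -> associated keywords.
# The canonical name itself is always a valid surface form and is added
# automatically on load; list here only the *additional* keywords.
# Keyword grouping is editable: copy this file, regroup, and pass it with
# --lexicon (or load_lexicon(path)).
Diabetes mellitus: [DM, Insulin, FBS, PPBS, IDDM]
Hypertension: [HTN]
Asthma: []
Acid peptic disease: [Gastric, Ulcer]
Hypothyroidism: []
Hyperthyroidism: []
Rheumatoid arthritis: [RA]
Allergy: []
Tuberculosis: []
Sinusitis: []
Arthritis: [Joint pain]
Coronary artery disease: [CAD, Cholesterol]
Migraine: []
Cancer: []
Paralysis: []
Spondylitis: []
Hepatitis: []
Epilepsy: [Fits, Seizures]
Malaria: []
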