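pt_code,pt_label,hlt,hlgt,soc
10016256,Tiredness,Asthenic conditions,General system disorders NEC,General disorders and administration site conditions
10048061,Weight decreased,Weight and nutrient analyses,Metabolic investigations,Investigations
10033371,Pain,Pain and discomfort NEC,General system disorders NEC,General disorders and administration site conditions
10016173,Faintness,Asthenic conditions,General system disorders NEC,General disorders and administration site conditions
10021097,Hypothyroidism,Thyroid hypofunction disorders,Thyroid gland disorders,Endocrine disorders
10020850,Hyperthyroidism,Thyroid hyperfunction disorders,Thyroid gland disorders,Endocrine disorders
10013573,Dizziness,Neurological signs and symptoms NEC,Neurological disorders NEC,Nervous system disorders
10022437,Insomnia,Disturbances in initiating and maintaining sleep,Sleep disorders,Psychiatric disorders
10033557,Palpitations,Cardiac signs and symptoms NEC,Cardiac disorders signs and symptoms,Cardiac disorders
10026749,Malignant tumor,Neoplasms malignant site unspecified,Neoplasms NEC,Neoplasms benign malignant and unspecified
10002855,Anxiety,Anxiety symptoms,Anxiety disorders and symptoms,Psychiatric disorders
10033295,Overdose,Overdoses NEC,Medication errors and overdoses,Injury poisoning and procedural complications
10029113,Nervous tension,Anxiety symptoms,Anxiety disorders and symptoms,Psychiatric disorders
10028411,Myalgia,Muscle pains,Musculoskeletal and connective tissue signs and symptoms,Musculoskeletal and connective tissue disorders
10028813,Nausea,Nausea and vomiting symptoms,Gastrointestinal signs and symptoms,Gastrointestinal disorders
10042209,Stress,Stress disorders,Anxiety disorders and symptoms,Psychiatric disorders
10012735,Diarrhea,Diarrhoea symptoms,Gastrointestinal motility and defaecation conditions,Gastrointestinal disorders
10043071,Tachycardia,Rate and rhythm disorders NEC,Cardiac arrhythmias,Cardiac disorders
10028334,Muscle spasms,Muscle related signs and symptoms NEC,Musculoskeletal and connective tissue signs and symptoms,Musculoskeletal and connective tissue disorders
10010904,Convulsions,Seizures NEC,Seizures,Nervous system disorders
10003239,Arthralgia,Joint related signs and symptoms,Joint disorders,Musculoskeletal and connective tissue disorders
10019211,Headache,Headaches NEC,Headaches,Nervous system disorders
10047700,Vomiting,Nausea and vomiting symptoms,Gastrointestinal signs and symptoms,Gastrointestinal disorders
10001540,Alopecia,Alopecias,Epidermal and dermal conditions,Skin and subcutaneous tissue disorders
10037844,Rash,Rashes eruptions and exanthems NEC,Epidermal and dermal conditions,Skin and subcutaneous tissue disorders
10034960,Pruritus,Pruritus NEC,Epidermal and dermal conditions,Skin and subcutaneous tissue disorders
10047340,Vertigo,Inner ear signs and symptoms,Inner ear and VIIIth cranial nerve disorders,Ear and labyrinth disorders
10012378,Depression,Depressive disorders,Mood disorders and disturbances NEC,Psychiatric disorders
10043890,Tremor,Tremor NEC,Movement disorders,Nervous system disorders
10047896,Weight increased,Weight and nutrient analyses,Metabolic investigations,Investigations
10010774,Constipation,Gastrointestinal atonic and hypomotility conditions NEC,Gastrointestinal motility and defaecation conditions,Gastrointestinal disorders
10000081,Abdominal pain,Gastrointestinal and abdominal pains,Gastrointestinal signs and symptoms,Gastrointestinal disorders
10037660,Psoriasis,Psoriatic conditions,Epidermal and dermal conditions,Skin and subcutaneous tissue disorders
10013968,Dyspnoea,Breathing abnormalities,Respiratory disorders NEC,Respiratory thoracic and mediastinal disorders
10011224,Cough,Coughing and associated symptoms,Respiratory disorders NEC,Respiratory thoracic and mediastinal disorders
10016558,Fever,Febrile disorders,Body temperature conditions,General disorders and administration site conditions
10030124,Oedema peripheral,Oedema NEC,General system disorders NEC,General disorders and administration site conditions
10019303,Hearing loss,Hearing losses,Hearing disorders,Ear and labyrinth disorders
10003988,Blurred vision,Visual disorders NEC,Vision disorders,Eye disorders
10013781,Dry mouth,Oral dryness and saliva altered,Oral soft tissue conditions,Gastrointestinal disorders
10020772,Hypertension,Vascular hypertensive disorders NEC,Vascular hypertensive disorders,Vascular disorders
10021118,Hypotension,Vascular hypotensive disorders,Decreased and nonspecific blood pressure disorders,Vascular disorders
10002034,Anaemia,Anaemias NEC,Anaemias nonhaemolytic and marrow depression,Blood and lymphatic system disorders
10024870,Loss of appetite,Appetite disorders,Appetite and general nutritional disorders,Metabolism and nutrition disorders
10022891,Irritability,Mood alterations with irritability symptoms,Mood disorders and disturbances NEC,Psychiatric disorders
10025482,Memory impairment,Memory loss,Mental impairment disorders,Nervous system disorders
10040984,Sleepiness,Disturbances in sleep phase rhythm,Sleep disorders,Psychiatric disorders
10019063,Hair loss,Alopecias,Epidermal and dermal conditions,Skin and subcutaneous tissue disorders
10030302,Oral paraesthesia,Paraesthesias and dysaesthesias,Neurological disorders NEC,Nervous system disorders
10016766,Flatulence,Flatulence bloating and distension,Gastrointestinal signs and symptoms,Gastrointestinal disorders
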