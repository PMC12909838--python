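# Data dictionary

Every coded clinical finding a diagnostic criterion reads, the record
section it is entered in, the closed time window (years from motor onset)
the reading criterion applies, and the criteria that read it. Findings are
tri-state: present / absent / unknown; unknown blocks classification.

Beyond these codes the criteria also read the cardinal-sign exam grid
(`exam.cardinal_signs`: bradykinesia, rigidity and rest tremor scored 0-4
per body region and side — essential criterion E1 and supportive criterion
S3), the medication list (`medications` — exclusion AE5), and disease
duration from `disease_onset_year` and `assessment_date` (red flag RF8).

| code | section | window (y) | read by | description |
|---|---|---|---|---|
| `cerebellar_gait` | exam | - | AE1 | Unequivocal cerebellar gait abnormality |
| `limb_ataxia` | exam | - | AE1 | Limb ataxia |
| `gaze_evoked_nystagmus` | exam | - | AE1 | Sustained gaze-evoked nystagmus |
| `macro_square_wave_jerks` | exam | - | AE1 | Macro square wave jerks |
| `hypermetric_saccades` | exam | - | AE1 | Hypermetric saccades |
| `downgaze_palsy` | exam | - | AE2 | Downward vertical supranuclear gaze palsy |
| `downward_saccade_slowing` | exam | - | AE2 | Selective slowing of downward vertical saccades |
| `cortical_sensory_loss` | exam | - | AE7 | Unequivocal cortical sensory loss (graphesthesia/stereognosis, primary modalities intact) |
| `limb_ideomotor_apraxia` | exam | - | AE7 | Clear limb ideomotor apraxia |
| `progressive_aphasia` | exam | - | AE7 | Progressive aphasia on examination |
| `pyramidal_tract_signs` | exam | - | RF9 | Otherwise unexplained pyramidal tract signs (pyramidal weakness or clear pathologic hyperreflexia) |
| `disproportionate_anterocollis` | exam | 10 | RF7 | Disproportionate (dystonic) anterocollis |
| `hand_or_foot_contractures` | exam | 10 | RF7 | Contractures of hand or feet |
| `bvftd_diagnosis` | health_profile | 5 | AE3 | Diagnosis of probable behavioural-variant frontotemporal dementia |
| `primary_progressive_aphasia_diagnosis` | health_profile | 5 | AE3 | Diagnosis of primary progressive aphasia |
| `lower_limb_restricted_parkinsonism_over_3y` | health_profile | - | AE4 | Parkinsonian features restricted to the lower limbs for more than 3 years |
| `drug_induced_course_consistent` | health_profile | - | AE5 | Dose and time-course of dopamine-blocking treatment consistent with drug-induced parkinsonism |
| `disease_severity_at_least_moderate` | health_profile | - | AE6 | Disease of at least moderate severity |
| `levodopa_observable_response` | health_profile | - | AE6 | Observable response to high-dose levodopa therapy |
| `alternative_condition_documented` | health_profile | - | AE9 | Documented alternative condition producing parkinsonism, plausibly connected to the symptoms |
| `dramatic_dopaminergic_response` | health_profile | - | S1 | Clear and dramatic beneficial response to dopaminergic therapy |
| `regular_wheelchair_use` | motor_symptoms | 5 | RF1 | Rapid progression of gait impairment requiring regular wheelchair use |
| `no_motor_progression_over_5y` | motor_symptoms | - | RF2 | Complete absence of progression of motor symptoms or signs over 5 or more years (not treatment-related) |
| `bilateral_symmetric_parkinsonism` | motor_symptoms | - | RF10 | Bilateral symmetric parkinsonism throughout the disease course |
| `marked_motor_fluctuations` | motor_symptoms | - | S1 | Marked on/off motor fluctuations, including predictable end-of-dose wearing-off |
| `levodopa_induced_dyskinesia` | motor_symptoms | - | S2 | Levodopa-induced dyskinesia |
| `rest_tremor_history` | motor_symptoms | - | S3 | Rest tremor of a limb, documented past or current |
| `severe_dysphonia_or_dysarthria` | non_motor_symptoms | 5 | RF3 | Severe dysphonia or dysarthria (speech unintelligible most of the time) |
| `severe_dysphagia` | non_motor_symptoms | 5 | RF3 | Severe dysphagia (requiring soft food, NG tube or gastrostomy feeding) |
| `inspiratory_stridor` | non_motor_symptoms | - | RF4 | Diurnal or nocturnal inspiratory stridor |
| `frequent_inspiratory_sigh` | non_motor_symptoms | - | RF4 | Frequent inspiratory sighs |
| `severe_orthostatic_hypotension` | non_motor_symptoms | 5 | RF5 | Severe orthostatic hypotension (>=30 mmHg systolic / >=15 mmHg diastolic within 3 min of standing) |
| `severe_urinary_dysfunction` | non_motor_symptoms | 5 | RF5 | Severe urinary retention or incontinence (not simply functional) |
| `recurrent_falls_from_balance` | non_motor_symptoms | 3 | RF6 | Recurrent (>1/year) falls because of impaired balance |
| `sleep_dysfunction` | non_motor_symptoms | - | RF8 | Sleep dysfunction (sleep-maintenance insomnia, excessive daytime somnolence, REM sleep behaviour disorder symptoms) |
| `autonomic_dysfunction_symptoms` | non_motor_symptoms | - | RF8 | Autonomic dysfunction (constipation, daytime urinary urgency, symptomatic orthostasis) |
| `hyposmia_symptom` | non_motor_symptoms | - | RF8 | Subjective or reported hyposmia |
| `psychiatric_dysfunction` | non_motor_symptoms | - | RF8 | Psychiatric dysfunction (depression, anxiety or hallucinations) |
| `dat_scan_normal` | diagnostics | - | AE8 | Normal functional neuroimaging of the presynaptic dopaminergic system |
| `olfactory_loss_documented` | diagnostics | - | S4 | Olfactory loss documented by formal testing |
| `mibg_cardiac_denervation` | diagnostics | - | S4 | Cardiac sympathetic denervation on MIBG scintigraphy |
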