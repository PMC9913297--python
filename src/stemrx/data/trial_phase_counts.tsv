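drug	phase	n_trials
Temozolomide	Phase 1	10
Temozolomide	Phase 1/2	4
Temozolomide	Phase 2	8
Temozolomide	Phase 3	1
Sirolimus	Phase 1	7
Sirolimus	Phase 1/2	4
Sirolimus	Phase 2	13
Sirolimus	Phase 3	2
Sirolimus	Phase 4	1
Sirolimus	Other	1
Propofol	Phase 2	1
Propofol	Phase 3	2
Propofol	Phase 4	7
Propofol	Other	19
Clarithromycin	Phase 1/2	2
Clarithromycin	Phase 2	10
Clarithromycin	Phase 3	3
Clarithromycin	Phase 4	1
Clarithromycin	Other	2
Simvastatin	Phase 1	4
Simvastatin	Phase 2	11
Simvastatin	Phase 3	1
Simvastatin	Phase 4	2
Disulfiram	Phase 1	4
Disulfiram	Phase 1/2	2
Disulfiram	Phase 2	6
Disulfiram	Phase 2/3	1
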