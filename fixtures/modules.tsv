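# planted ground-truth modules; spec: 50x40, 4 modules, p_in=0.5, p_out=0.02, sim_signal=0.8, seed=1
node	type	module
T000	target	0
T001	target	0
T002	target	0
T003	target	0
T004	target	0
T005	target	0
T006	target	0
T007	target	0
T008	target	0
T009	target	0
T010	target	1
T011	target	1
T012	target	1
T013	target	1
T014	target	1
T015	target	1
T016	target	1
T017	target	1
T018	target	1
T019	target	1
T020	target	2
T021	target	2
T022	target	2
T023	target	2
T024	target	2
T025	target	2
T026	target	2
T027	target	2
T028	target	2
T029	target	2
T030	target	3
T031	target	3
T032	target	3
T033	target	3
T034	target	3
T035	target	3
T036	target	3
T037	target	3
T038	target	3
T039	target	3
D000	drug	0
D001	drug	0
D002	drug	0
D003	drug	0
D004	drug	0
D005	drug	0
D006	drug	0
D007	drug	0
D008	drug	0
D009	drug	0
D010	drug	0
D011	drug	0
D012	drug	1
D013	drug	1
D014	drug	1
D015	drug	1
D016	drug	1
D017	drug	1
D018	drug	1
D019	drug	1
D020	drug	1
D021	drug	1
D022	drug	1
D023	drug	1
D024	drug	1
D025	drug	2
D026	drug	2
D027	drug	2
D028	drug	2
D029	drug	2
D030	drug	2
D031	drug	2
D032	drug	2
D033	drug	2
D034	drug	2
D035	drug	2
D036	drug	2
D037	drug	3
D038	drug	3
D039	drug	3
D040	drug	3
D041	drug	3
D042	drug	3
D043	drug	3
D044	drug	3
D045	drug	3
D046	drug	3
D047	drug	3
D048	drug	3
D049	drug	3
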