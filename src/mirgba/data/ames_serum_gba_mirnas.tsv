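mirna	family	cpm	fc_normal	p_normal	fdr_normal	fc_dwarf	p_dwarf	fdr_dwarf	fc_gba	p_gba	fdr_gba	pattern
mmu-miR-5107-5p	mir-5107	8	9.9	0.000	0.000	1.3	0.916	1.000	-7.8	0.002	0.079	A
mmu-miR-146a-5p	mir-146	165	5.4	0.000	0.000	1.2	0.812	1.000	-4.4	0.003	0.096	A
mmu-miR-342-5p	mir-342	60	3.0	0.000	0.001	1.1	0.920	1.000	-2.8	0.002	0.084	A
mmu-miR-344d-3-5p	mir-344	3	-7.1	0.000	0.004	2.3	0.329	0.788	16.5	0.001	0.058	B
mmu-miR-376c-5p	mir-368	5	-30.0	0.000	0.000	-1.7	0.248	0.753	17.4	0.002	0.074	B
mmu-miR-136-5p	mir-136	156	-15.4	0.000	0.000	-1.6	0.205	0.731	9.7	0.002	0.079	B
mmu-miR-411-5p	mir-379	33	-19.2	0.000	0.000	-1.6	0.249	0.753	12.1	0.002	0.074	B
mmu-miR-344d-1-5p	mir-344	3	-8.4	0.000	0.004	1.5	0.330	0.788	12.3	0.001	0.058	B
mmu-miR-410-5p	mir-154	58	-8.3	0.000	0.000	-1.3	0.434	0.875	6.3	0.002	0.076	B
mmu-miR-369-5p	mir-154	5	-31.8	0.000	0.000	-1.5	0.436	0.876	21.4	0.000	0.058	B
mmu-miR-154-5p	mir-154	7	-63.9	0.000	0.000	-1.5	0.435	0.876	41.6	0.001	0.059	B
mmu-miR-540-5p	mir-540	6	-23.8	0.000	0.000	-1.3	0.526	0.958	17.7	0.001	0.058	B
mmu-miR-127-5p	mir-127	498	-19.4	0.000	0.000	-1.2	0.496	0.925	16.0	0.000	0.058	B
mmu-miR-449a-5p	mir-449	3	-4.0	0.000	0.000	1.1	0.935	1.000	4.3	0.001	0.059	B
mmu-miR-381-5p	mir-154	77	-15.2	0.000	0.000	-1.1	0.790	1.000	13.7	0.001	0.058	B
mmu-miR-344d-3p	mir-344	3	-4.7	0.000	0.004	1.7	0.330	0.788	8.1	0.001	0.058	B
mmu-miR-195a-5p	mir-15	56	-3.2	0.000	0.000	-1.0	0.972	1.000	3.2	0.001	0.058	B
mmu-miR-34c-5p	mir-34	28	-5.1	0.000	0.003	4.1	0.005	0.118	20.9	0.000	0.004	C
mmu-miR-34b-5p	mir-34	7	-2.7	0.018	0.087	3.3	0.008	0.145	9.0	0.000	0.058	C
mmu-miR-344d-2-5p	mir-344	3	-4.8	0.000	0.004	2.4	0.329	0.788	11.3	0.001	0.058	C
mmu-miR-592-5p	mir-592	10	1.2	0.906	1.000	20.8	0.000	0.000	17.3	0.000	0.058	D
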