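taxon	group	n	pi	theta_w	tajimas_d	d_significant	gst	gst_significant
Fungi1	fungi	52	0.0088	0.0244	-2.1585	1	0.1099	1
Fungi2	fungi	51	0.0130	0.0299	-2.0211	1	0.2335	0
Fungi3	fungi	22	0.0157	0.0272	-1.7148	0	0.1419	0
Fungi4	fungi	2507	0.0059	0.0918	-2.6902	1	0.0025	0
Fungi5	fungi	97	0.0072	0.0203	-2.0520	1	0.0514	0
Fungi6	fungi	168	0.0090	0.0187	-1.6674	0	0.0167	0
Fungi7	fungi	84	0.0088	0.0217	-2.0016	1	0.0711	0
Fungi8	fungi	57	0.0134	0.0341	-2.0901	1	0.1150	0
Fungi9	fungi	30	0.0010	0.0053	-2.3512	1	0.0991	0
Fungi10	fungi	54	0.0050	0.0183	-2.3958	1	0.0788	0
Fungi11	fungi	189	0.0078	0.0307	-2.3694	1	0.0090	0
Fungi12	fungi	14	0.0087	0.0100	-0.6488	0	0.2805	0
Fungi13	fungi	40	0.0103	0.0125	-0.6810	0	0.2494	0
Fungi14	fungi	766	0.0117	0.0586	-2.4374	1	0.0052	0
Fungi15	fungi	15	0.0106	0.0188	-1.8028	1	0.0451	0
Amoebozoa1	amoebozoa	227	0.0042	0.0347	-2.6856	1	0.0411	0
Alveolata1	alveolata	18	0.0182	0.0324	-1.8094	1	0.0418	0
Nematoda1	nematoda	79	0.0150	0.0317	-1.8654	1	0.4101	0
Nematoda2	nematoda	154	0.0130	0.0174	-0.9456	0	0.2359	0
Nematoda3	nematoda	21	0.0188	0.0170	0.2858	0	0.0624	0
Insect1	insecta	61	0.0122	0.0285	-2.0101	1	0.0346	0
Insect2	insecta	37	0.0208	0.0409	-1.8296	1	0.0723	0
Insect3	insecta	41	0.0081	0.0208	-2.1225	1	0.2694	0
Mite1	acari	828	0.0086	0.0620	-2.5727	1	0.0150	1
Mite2	acari	30	0.0152	0.0348	-2.1831	1	0.2911	0
Mite3	acari	1071	0.0071	0.0678	-2.6276	1	0.0101	1
Mite4	acari	56	0.0114	0.0242	-1.7765	0	0.0437	0
Mite5	acari	34	0.0176	0.0219	-0.7551	0	0.1516	0
Mite6	acari	50	0.0111	0.0197	-1.4951	0	0.0427	0
Mite7	acari	45	0.0049	0.0098	-1.5594	0	0.0147	0
Unknown	unknown	66	0.0059	0.0198	-2.2971	1	0.3539	0
HostPlant	host_plant	79	0.0028	0.0034	-0.4521	0	0.8483	1
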