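sample_id	date	day_night	top_m	bottom_m	filtered_volume_m3	aliquot_fraction	mesh_um	mouth_area_m2
oct_d_L1	2010-10-29	D	0	50	150.0	1/32	335	1.5
oct_d_L2	2010-10-29	D	50	100	150.0	1/16	335	1.5
oct_d_L3	2010-10-29	D	100	150	150.0	1/16	335	1.5
oct_d_L4	2010-10-29	D	150	200	150.0	1/8	335	1.5
oct_d_L5	2010-10-29	D	200	300	300.0	1/8	335	1.5
oct_d_L6	2010-10-29	D	300	500	600.0	1/8	335	1.5
oct_d_L7	2010-10-29	D	500	750	750.0	1/4	335	1.5
oct_d_L8	2010-10-29	D	750	1000	750.0	1/2	335	1.5
oct_n_L1	2010-10-29	N	0	50	150.0	1/32	335	1.5
oct_n_L2	2010-10-29	N	50	100	150.0	1/16	335	1.5
oct_n_L3	2010-10-29	N	100	150	150.0	1/16	335	1.5
oct_n_L4	2010-10-29	N	150	200	150.0	1/8	335	1.5
oct_n_L5	2010-10-29	N	200	300	300.0	1/8	335	1.5
oct_n_L6	2010-10-29	N	300	500	600.0	1/8	335	1.5
oct_n_L7	2010-10-29	N	500	750	750.0	1/4	335	1.5
oct_n_L8	2010-10-29	N	750	1000	750.0	1/2	335	1.5
feb_d_L1	2011-02-26	D	0	50	150.0	1/32	335	1.5
feb_d_L2	2011-02-26	D	50	100	150.0	1/16	335	1.5
feb_d_L3	2011-02-26	D	100	150	150.0	1/16	335	1.5
feb_d_L4	2011-02-26	D	150	200	150.0	1/8	335	1.5
feb_d_L5	2011-02-26	D	200	300	300.0	1/8	335	1.5
feb_d_L6	2011-02-26	D	300	500	600.0	1/8	335	1.5
feb_d_L7	2011-02-26	D	500	750	750.0	1/4	335	1.5
feb_d_L8	2011-02-26	D	750	1000	750.0	1/2	335	1.5
feb_n_L1	2011-02-26	N	0	50	150.0	1/32	335	1.5
feb_n_L2	2011-02-26	N	50	100	150.0	1/16	335	1.5
feb_n_L3	2011-02-26	N	100	150	150.0	1/16	335	1.5
feb_n_L4	2011-02-26	N	150	200	150.0	1/8	335	1.5
feb_n_L5	2011-02-26	N	200	300	300.0	1/8	335	1.5
feb_n_L6	2011-02-26	N	300	500	600.0	1/8	335	1.5
feb_n_L7	2011-02-26	N	500	750	750.0	1/4	335	1.5
feb_n_L8	2011-02-26	N	750	1000	750.0	1/2	335	1.5
apr_d_L1	2011-04-22	D	0	50	150.0	1/32	335	1.5
apr_d_L2	2011-04-22	D	50	100	150.0	1/16	335	1.5
apr_d_L3	2011-04-22	D	100	150	150.0	1/16	335	1.5
apr_d_L4	2011-04-22	D	150	200	150.0	1/8	335	1.5
apr_d_L5	2011-04-22	D	200	300	300.0	1/8	335	1.5
apr_d_L6	2011-04-22	D	300	500	600.0	1/8	335	1.5
apr_d_L7	2011-04-22	D	500	750	750.0	1/4	335	1.5
apr_d_L8	2011-04-22	D	750	1000	750.0	1/2	335	1.5
apr_n_L1	2011-04-22	N	0	50	150.0	1/32	335	1.5
apr_n_L2	2011-04-22	N	50	100	150.0	1/16	335	1.5
apr_n_L3	2011-04-22	N	100	150	150.0	1/16	335	1.5
apr_n_L4	2011-04-22	N	150	200	150.0	1/8	335	1.5
apr_n_L5	2011-04-22	N	200	300	300.0	1/8	335	1.5
apr_n_L6	2011-04-22	N	300	500	600.0	1/8	335	1.5
apr_n_L7	2011-04-22	N	500	750	750.0	1/4	335	1.5
apr_n_L8	2011-04-22	N	750	1000	750.0	1/2	335	1.5
jul_d_L1	2011-07-03	D	0	50	150.0	1/32	335	1.5
jul_d_L2	2011-07-03	D	50	100	150.0	1/16	335	1.5
jul_d_L3	2011-07-03	D	100	150	150.0	1/16	335	1.5
jul_d_L4	2011-07-03	D	150	200	150.0	1/8	335	1.5
jul_d_L5	2011-07-03	D	200	300	300.0	1/8	335	1.5
jul_d_L6	2011-07-03	D	300	500	600.0	1/8	335	1.5
jul_d_L7	2011-07-03	D	500	750	750.0	1/4	335	1.5
jul_d_L8	2011-07-03	D	750	1000	750.0	1/2	335	1.5
jul_n_L1	2011-07-04	N	0	50	150.0	1/32	335	1.5
jul_n_L2	2011-07-04	N	50	100	150.0	1/16	335	1.5
jul_n_L3	2011-07-04	N	100	150	150.0	1/16	335	1.5
jul_n_L4	2011-07-04	N	150	200	150.0	1/8	335	1.5
jul_n_L5	2011-07-04	N	200	300	300.0	1/8	335	1.5
jul_n_L6	2011-07-04	N	300	500	600.0	1/8	335	1.5
jul_n_L7	2011-07-04	N	500	750	750.0	1/4	335	1.5
jul_n_L8	2011-07-04	N	750	1000	750.0	1/2	335	1.5
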