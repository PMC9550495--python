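no	combination	acc	sn	ppv	fscore	auc
1	ABCDEF	0.725	0.809	0.753	0.779	0.790
2	ABCDE	0.717	0.799	0.749	0.773	0.774
3	ABCDF	0.723	0.811	0.751	0.779	0.790
4	ABCEF	0.723	0.810	0.751	0.778	0.787
5	ABDEF	0.710	0.814	0.733	0.771	0.770
6	ACDEF	0.720	0.815	0.744	0.778	0.780
7	BCDEF	0.724	0.807	0.753	0.778	0.786
8	ABCD	0.719	0.804	0.749	0.774	0.771
9	ABCE	0.718	0.798	0.751	0.773	0.771
10	ABCF	0.724	0.808	0.754	0.780	0.786
11	ABDE	0.698	0.810	0.722	0.763	0.753
12	ABDF	0.711	0.817	0.734	0.773	0.771
13	ABEF	0.708	0.807	0.735	0.769	0.771
14	ACDE	0.711	0.813	0.735	0.771	0.766
15	ACDF	0.722	0.821	0.744	0.780	0.782
16	ACEF	0.719	0.814	0.743	0.777	0.780
17	ADEF	0.703	0.847	0.714	0.775	0.745
18	BCDE	0.718	0.797	0.751	0.773	0.771
19	BCDF	0.723	0.806	0.753	0.778	0.787
20	BCEF	0.719	0.799	0.752	0.774	0.783
21	BDEF	0.710	0.811	0.735	0.771	0.773
22	CDEF	0.720	0.812	0.746	0.777	0.780
23	ABC	0.718	0.802	0.749	0.774	0.771
24	ABD	0.699	0.818	0.720	0.765	0.753
25	ABE	0.697	0.810	0.721	0.763	0.754
26	ABF	0.709	0.810	0.735	0.770	0.773
27	ACD	0.712	0.816	0.735	0.773	0.762
28	ACE	0.707	0.807	0.734	0.768	0.760
29	ACF	0.720	0.819	0.743	0.779	0.783
30	ADE	0.679	0.827	0.696	0.755	0.705
31	ADF	0.703	0.844	0.715	0.774	0.745
32	AEF	0.701	0.836	0.716	0.771	0.739
33	BCD	0.718	0.799	0.750	0.773	0.773
34	BCE	0.713	0.785	0.751	0.767	0.767
35	BCF	0.716	0.796	0.749	0.771	0.777
36	BDE	0.699	0.811	0.723	0.764	0.754
37	BDF	0.712	0.816	0.735	0.773	0.773
38	BEF	0.705	0.798	0.735	0.765	0.771
39	CDE	0.712	0.808	0.738	0.771	0.767
40	CDF	0.722	0.819	0.745	0.780	0.783
41	CEF	0.721	0.817	0.745	0.779	0.780
42	DEF	0.703	0.835	0.718	0.772	0.748
43	AB	0.695	0.815	0.717	0.763	0.740
44	AC	0.708	0.820	0.729	0.772	0.760
45	AD	0.673	0.848	0.684	0.757	0.691
46	AE	0.676	0.846	0.688	0.759	0.693
47	AF	0.700	0.847	0.711	0.773	0.739
48	BC	0.707	0.789	0.742	0.764	0.755
49	BD	0.699	0.815	0.721	0.765	0.756
50	BE	0.694	0.802	0.722	0.759	0.750
51	BF	0.702	0.793	0.734	0.761	0.766
52	CD	0.713	0.817	0.736	0.774	0.764
53	CE	0.704	0.795	0.736	0.764	0.759
54	CF	0.713	0.813	0.737	0.772	0.773
55	DE	0.677	0.830	0.693	0.755	0.703
56	DF	0.702	0.840	0.716	0.772	0.746
57	EF	0.697	0.828	0.715	0.767	0.740
58	A	0.664	0.867	0.667	0.759	0.662
59	B	0.674	0.796	0.703	0.745	0.729
60	C	0.691	0.811	0.714	0.759	0.738
61	D	0.670	0.842	0.684	0.754	0.693
62	E	0.670	0.838	0.685	0.754	0.690
63	F	0.685	0.842	0.697	0.763	0.726
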