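# synthetic pairwise contact-potential matrix (stand-in; not a published table)
	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	2.718	0.220	-1.102	-2.152	-1.691	0.779	1.248	1.822	0.685	-0.064	-1.047	0.621	0.326	-0.944	0.169	-0.980	-1.293	0.201	-0.788	0.181
C	0.220	0.883	1.045	-1.431	0.744	1.578	-0.138	0.971	-0.471	2.095	-0.020	0.889	0.292	-3.346	-1.417	-0.509	-0.942	1.720	1.492	-0.686
D	-1.102	1.045	0.422	0.017	-1.699	-0.148	-1.570	-1.220	0.156	1.398	1.205	-0.490	-0.130	-0.460	1.013	-0.491	-0.352	1.385	-0.125	-0.777
E	-2.152	-1.431	0.017	0.239	1.019	0.101	-0.257	-0.722	-1.746	-0.539	0.708	-0.130	1.460	-0.873	-0.057	-0.415	-0.823	0.477	-0.156	0.505
F	-1.691	0.744	-1.699	1.019	0.143	-0.023	0.530	1.198	0.949	-0.397	0.393	-1.376	-0.477	0.057	-2.500	0.372	0.174	0.127	-1.427	-1.900
G	0.779	1.578	-0.148	0.101	-0.023	2.396	-2.515	0.686	-0.097	0.994	0.575	-0.338	-1.061	1.876	-0.702	-0.250	2.265	-1.374	0.760	0.450
H	1.248	-0.138	-1.570	-0.257	0.530	-2.515	1.618	2.145	-1.005	-2.845	1.203	1.200	-1.333	-0.758	0.485	0.767	-1.537	0.357	-0.231	-0.947
I	1.822	0.971	-1.220	-0.722	1.198	0.686	2.145	1.906	-0.557	-0.133	0.522	0.137	-1.558	-0.000	-0.655	-0.454	1.047	-0.030	1.037	0.045
K	0.685	-0.471	0.156	-1.746	0.949	-0.097	-1.005	-0.557	1.699	-1.780	0.046	0.934	1.882	2.072	-0.627	-0.742	-1.616	1.087	-0.551	0.156
L	-0.064	2.095	1.398	-0.539	-0.397	0.994	-2.845	-0.133	-1.780	-1.445	1.021	1.202	-1.251	1.499	0.276	0.053	-0.176	-0.683	0.690	0.558
M	-1.047	-0.020	1.205	0.708	0.393	0.575	1.203	0.522	0.046	1.021	1.134	0.707	-0.258	-0.091	-0.869	1.224	-0.009	-0.111	-1.207	0.421
N	0.621	0.889	-0.490	-0.130	-1.376	-0.338	1.200	0.137	0.934	1.202	0.707	-0.258	-1.575	0.936	1.043	1.157	-0.669	3.258	0.054	-0.213
P	0.326	0.292	-0.130	1.460	-0.477	-1.061	-1.333	-1.558	1.882	-1.251	-0.258	-1.575	-2.234	-1.306	-0.963	-1.018	-0.014	0.697	-0.118	-0.489
Q	-0.944	-3.346	-0.460	-0.873	0.057	1.876	-0.758	-0.000	2.072	1.499	-0.091	0.936	-1.306	1.273	-2.199	0.319	1.849	-2.149	-2.814	-1.544
R	0.169	-1.417	1.013	-0.057	-2.500	-0.702	0.485	-0.655	-0.627	0.276	-0.869	1.043	-0.963	-2.199	-2.042	-0.946	-0.904	0.910	0.645	-0.276
S	-0.980	-0.509	-0.491	-0.415	0.372	-0.250	0.767	-0.454	-0.742	0.053	1.224	1.157	-1.018	0.319	-0.946	-0.448	0.291	-2.551	0.167	0.038
T	-1.293	-0.942	-0.352	-0.823	0.174	2.265	-1.537	1.047	-1.616	-0.176	-0.009	-0.669	-0.014	1.849	-0.904	0.291	2.161	0.829	-0.079	1.355
V	0.201	1.720	1.385	0.477	0.127	-1.374	0.357	-0.030	1.087	-0.683	-0.111	3.258	0.697	-2.149	0.910	-2.551	0.829	1.294	-1.545	-1.258
W	-0.788	1.492	-0.125	-0.156	-1.427	0.760	-0.231	1.037	-0.551	0.690	-1.207	0.054	-0.118	-2.814	0.645	0.167	-0.079	-1.545	0.531	0.255
Y	0.181	-0.686	-0.777	0.505	-1.900	0.450	-0.947	0.045	0.156	0.558	0.421	-0.213	-0.489	-1.544	-0.276	0.038	1.355	-1.258	0.255	1.001
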