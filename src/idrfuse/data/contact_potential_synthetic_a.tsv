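# synthetic pairwise contact-potential matrix (stand-in; not a published table)
	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-1.185	-1.594	-0.605	-0.050	0.372	-0.618	1.640	-0.319	0.832	-0.495	-0.290	1.678	-0.889	-0.859	-0.579	-0.860	0.706	1.878	1.566	-0.404
C	-1.594	1.281	1.984	0.341	-1.019	0.062	0.794	0.275	1.632	1.444	-1.554	-0.809	-1.029	0.268	-1.067	2.785	-1.077	-0.600	0.691	0.532
D	-0.605	1.984	2.194	2.122	-0.373	-1.337	-1.374	-0.027	0.224	0.311	1.027	0.833	1.212	0.095	-1.967	-1.482	-1.381	-0.736	0.407	-0.935
E	-0.050	0.341	2.122	0.122	1.213	-0.664	-1.270	-0.964	0.407	0.347	0.828	1.576	-1.092	2.021	-0.189	-1.779	-0.893	-2.523	0.933	-1.839
F	0.372	-1.019	-0.373	1.213	-0.109	-0.955	-0.678	0.974	0.643	0.329	-0.975	-1.767	-1.034	-1.606	0.701	0.169	-0.395	0.869	1.799	-0.514
G	-0.618	0.062	-1.337	-0.664	-0.955	-0.906	0.811	-0.484	-0.582	-0.319	-1.436	1.408	-0.068	1.105	0.186	-1.077	1.405	-1.734	-0.559	-0.637
H	1.640	0.794	-1.374	-1.270	-0.678	0.811	-1.712	-0.507	0.727	0.816	-0.691	-1.225	-0.362	0.277	0.469	-0.628	-1.417	0.072	-0.211	1.517
I	-0.319	0.275	-0.027	-0.964	0.974	-0.484	-0.507	2.230	-0.567	-0.622	-0.760	-0.854	-0.580	-2.025	-1.673	-2.816	1.325	0.823	0.820	-0.217
K	0.832	1.632	0.224	0.407	0.643	-0.582	0.727	-0.567	-1.545	1.525	-1.129	-1.411	-0.042	0.868	-0.669	0.455	1.734	-0.566	-0.584	-0.100
L	-0.495	1.444	0.311	0.347	0.329	-0.319	0.816	-0.622	1.525	-1.992	-0.527	0.923	-1.490	1.434	-0.034	0.569	0.687	1.854	-0.582	0.798
M	-0.290	-1.554	1.027	0.828	-0.975	-1.436	-0.691	-0.760	-1.129	-0.527	1.106	0.866	0.337	0.474	0.524	1.046	-1.453	-1.677	-1.380	0.616
N	1.678	-0.809	0.833	1.576	-1.767	1.408	-1.225	-0.854	-1.411	0.923	0.866	0.655	-0.879	0.431	0.161	0.116	0.500	0.841	0.367	1.222
P	-0.889	-1.029	1.212	-1.092	-1.034	-0.068	-0.362	-0.580	-0.042	-1.490	0.337	-0.879	-0.989	-0.102	-1.331	-0.301	-1.771	0.372	-0.568	0.986
Q	-0.859	0.268	0.095	2.021	-1.606	1.105	0.277	-2.025	0.868	1.434	0.474	0.431	-0.102	-0.270	0.614	0.437	-0.546	0.181	0.893	-0.007
R	-0.579	-1.067	-1.967	-0.189	0.701	0.186	0.469	-1.673	-0.669	-0.034	0.524	0.161	-1.331	0.614	0.233	0.957	-0.770	-0.039	-1.385	0.611
S	-0.860	2.785	-1.482	-1.779	0.169	-1.077	-0.628	-2.816	0.455	0.569	1.046	0.116	-0.301	0.437	0.957	-1.430	-0.747	1.206	-0.210	-0.736
T	0.706	-1.077	-1.381	-0.893	-0.395	1.405	-1.417	1.325	1.734	0.687	-1.453	0.500	-1.771	-0.546	-0.770	-0.747	2.924	0.370	0.798	-0.764
V	1.878	-0.600	-0.736	-2.523	0.869	-1.734	0.072	0.823	-0.566	1.854	-1.677	0.841	0.372	0.181	-0.039	1.206	0.370	0.206	-0.289	-0.791
W	1.566	0.691	0.407	0.933	1.799	-0.559	-0.211	0.820	-0.584	-0.582	-1.380	0.367	-0.568	0.893	-1.385	-0.210	0.798	-0.289	-0.013	-0.688
Y	-0.404	0.532	-0.935	-1.839	-0.514	-0.637	1.517	-0.217	-0.100	0.798	0.616	1.222	0.986	-0.007	0.611	-0.736	-0.764	-0.791	-0.688	-1.275
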