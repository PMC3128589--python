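# Synthetic residue-residue contact-energy matrix (model units).
# Built from the Kyte-Doolittle hydropathy scale via the
# additive+multiplicative decomposition e(a,b) = c0 + c1*(h_a+h_b) + c2*h_a*h_b
# (h rescaled to [-1,1]; c0=-0.30 c1=-0.275 c2=-0.35). Stand-in for a
# PDB-derived statistical contact potential; symmetric by construction.
	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.576	-0.641	-0.087	-0.087	-0.668	-0.373	-0.115	-0.825	-0.050	-0.760	-0.585	-0.087	-0.262	-0.087	0.005	-0.336	-0.345	-0.797	-0.327	-0.290
C	-0.641	-0.714	-0.088	-0.088	-0.745	-0.411	-0.119	-0.922	-0.046	-0.849	-0.651	-0.088	-0.286	-0.088	0.017	-0.369	-0.380	-0.891	-0.359	-0.317
D	-0.087	-0.088	-0.084	-0.084	-0.088	-0.086	-0.084	-0.089	-0.084	-0.088	-0.087	-0.084	-0.085	-0.084	-0.083	-0.086	-0.086	-0.089	-0.086	-0.085
E	-0.087	-0.088	-0.084	-0.084	-0.088	-0.086	-0.084	-0.089	-0.084	-0.088	-0.087	-0.084	-0.085	-0.084	-0.083	-0.086	-0.086	-0.089	-0.086	-0.085
F	-0.668	-0.745	-0.088	-0.088	-0.778	-0.427	-0.121	-0.964	-0.044	-0.887	-0.679	-0.088	-0.296	-0.088	0.022	-0.384	-0.394	-0.931	-0.373	-0.329
G	-0.373	-0.411	-0.086	-0.086	-0.427	-0.254	-0.102	-0.519	-0.064	-0.482	-0.379	-0.086	-0.189	-0.086	-0.032	-0.232	-0.238	-0.503	-0.227	-0.205
H	-0.115	-0.119	-0.084	-0.084	-0.121	-0.102	-0.086	-0.131	-0.082	-0.126	-0.115	-0.084	-0.095	-0.084	-0.078	-0.100	-0.100	-0.129	-0.099	-0.097
I	-0.825	-0.922	-0.089	-0.089	-0.964	-0.519	-0.131	-1.200	-0.033	-1.103	-0.839	-0.089	-0.353	-0.089	0.050	-0.464	-0.478	-1.158	-0.450	-0.394
K	-0.050	-0.046	-0.084	-0.084	-0.044	-0.064	-0.082	-0.033	-0.086	-0.038	-0.050	-0.084	-0.072	-0.084	-0.090	-0.067	-0.066	-0.035	-0.067	-0.070
L	-0.760	-0.849	-0.088	-0.088	-0.887	-0.482	-0.126	-1.103	-0.038	-1.014	-0.773	-0.088	-0.329	-0.088	0.038	-0.431	-0.443	-1.065	-0.418	-0.367
M	-0.585	-0.651	-0.087	-0.087	-0.679	-0.379	-0.115	-0.839	-0.050	-0.773	-0.595	-0.087	-0.266	-0.087	0.007	-0.341	-0.350	-0.811	-0.332	-0.294
N	-0.087	-0.088	-0.084	-0.084	-0.088	-0.086	-0.084	-0.089	-0.084	-0.088	-0.087	-0.084	-0.085	-0.084	-0.083	-0.086	-0.086	-0.089	-0.086	-0.085
P	-0.262	-0.286	-0.085	-0.085	-0.296	-0.189	-0.095	-0.353	-0.072	-0.329	-0.266	-0.085	-0.149	-0.085	-0.052	-0.175	-0.179	-0.343	-0.172	-0.159
Q	-0.087	-0.088	-0.084	-0.084	-0.088	-0.086	-0.084	-0.089	-0.084	-0.088	-0.087	-0.084	-0.085	-0.084	-0.083	-0.086	-0.086	-0.089	-0.086	-0.085
R	0.005	0.017	-0.083	-0.083	0.022	-0.032	-0.078	0.050	-0.090	0.038	0.007	-0.083	-0.052	-0.083	-0.100	-0.038	-0.037	0.045	-0.040	-0.047
S	-0.336	-0.369	-0.086	-0.086	-0.384	-0.232	-0.100	-0.464	-0.067	-0.431	-0.341	-0.086	-0.175	-0.086	-0.038	-0.213	-0.218	-0.450	-0.209	-0.190
T	-0.345	-0.380	-0.086	-0.086	-0.394	-0.238	-0.100	-0.478	-0.066	-0.443	-0.350	-0.086	-0.179	-0.086	-0.037	-0.218	-0.223	-0.463	-0.213	-0.194
V	-0.797	-0.891	-0.089	-0.089	-0.931	-0.503	-0.129	-1.158	-0.035	-1.065	-0.811	-0.089	-0.343	-0.089	0.045	-0.450	-0.463	-1.118	-0.436	-0.383
W	-0.327	-0.359	-0.086	-0.086	-0.373	-0.227	-0.099	-0.450	-0.067	-0.418	-0.332	-0.086	-0.172	-0.086	-0.040	-0.209	-0.213	-0.436	-0.204	-0.186
Y	-0.290	-0.317	-0.085	-0.085	-0.329	-0.205	-0.097	-0.394	-0.070	-0.367	-0.294	-0.085	-0.159	-0.085	-0.047	-0.190	-0.194	-0.383	-0.186	-0.170
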