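# Default detector selection: 91 configurations over seven families
# (LOF 15, KNN 10, AvgKNN 16, CBLOF 15, OCSVM 5, FeatureBagging 15, LSCP 15).
# The per-family counts follow the published post-selection pool; the
# individual hyperparameter picks within each family are a synthetic,
# deterministic stand-in (smallest grid values first) since the original
# per-config list is not distributed.
version: 1
selection:
- LOF_k5_euclidean
- LOF_k5_manhattan
- LOF_k5_chebyshev
- LOF_k10_euclidean
- LOF_k10_manhattan
- LOF_k10_chebyshev
- LOF_k15_euclidean
- LOF_k15_manhattan
- LOF_k15_chebyshev
- LOF_k20_euclidean
- LOF_k20_manhattan
- LOF_k20_chebyshev
- LOF_k25_euclidean
- LOF_k25_manhattan
- LOF_k25_chebyshev
- KNN_k3_euclidean
- KNN_k3_manhattan
- KNN_k5_euclidean
- KNN_k5_manhattan
- KNN_k8_euclidean
- KNN_k8_manhattan
- KNN_k10_euclidean
- KNN_k10_manhattan
- KNN_k15_euclidean
- KNN_k15_manhattan
- AvgKNN_k3_euclidean
- AvgKNN_k3_manhattan
- AvgKNN_k5_euclidean
- AvgKNN_k5_manhattan
- AvgKNN_k8_euclidean
- AvgKNN_k8_manhattan
- AvgKNN_k10_euclidean
- AvgKNN_k10_manhattan
- AvgKNN_k15_euclidean
- AvgKNN_k15_manhattan
- AvgKNN_k20_euclidean
- AvgKNN_k20_manhattan
- AvgKNN_k25_euclidean
- AvgKNN_k25_manhattan
- AvgKNN_k30_euclidean
- AvgKNN_k30_manhattan
- CBLOF_c4_s0
- CBLOF_c4_s1
- CBLOF_c4_s2
- CBLOF_c6_s0
- CBLOF_c6_s1
- CBLOF_c6_s2
- CBLOF_c8_s0
- CBLOF_c8_s1
- CBLOF_c8_s2
- CBLOF_c10_s0
- CBLOF_c10_s1
- CBLOF_c10_s2
- CBLOF_c12_s0
- CBLOF_c12_s1
- CBLOF_c12_s2
- OCSVM_rbf_nu0.05
- OCSVM_rbf_nu0.1
- OCSVM_rbf_nu0.2
- OCSVM_rbf_nu0.3
- OCSVM_rbf_nu0.4
- FeatureBagging_e5_s0
- FeatureBagging_e5_s1
- FeatureBagging_e5_s2
- FeatureBagging_e5_s3
- FeatureBagging_e5_s4
- FeatureBagging_e10_s0
- FeatureBagging_e10_s1
- FeatureBagging_e10_s2
- FeatureBagging_e10_s3
- FeatureBagging_e10_s4
- FeatureBagging_e15_s0
- FeatureBagging_e15_s1
- FeatureBagging_e15_s2
- FeatureBagging_e15_s3
- FeatureBagging_e15_s4
- LSCP_p4_s0
- LSCP_p4_s1
- LSCP_p4_s2
- LSCP_p4_s3
- LSCP_p4_s4
- LSCP_p6_s0
- LSCP_p6_s1
- LSCP_p6_s2
- LSCP_p6_s3
- LSCP_p6_s4
- LSCP_p8_s0
- LSCP_p8_s1
- LSCP_p8_s2
- LSCP_p8_s3
- LSCP_p8_s4
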