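# The 195 radiomic feature names in extraction order.
# Pattern: family.name[.dD_oNN] with D the GLCM distance and NN the offset index.
clinical.age
clinical.gender
location.left_frontal
location.right_frontal
location.left_parietal
location.right_parietal
location.left_temporal
location.right_temporal
location.left_occipital
location.right_occipital
location.left_limbic
location.right_limbic
location.left_sublobar
location.right_sublobar
location.left_cerebellum
location.right_cerebellum
location.left_brainstem
location.right_brainstem
morph.volume_mm3
morph.equiv_diameter_mm
morph.extent
morph.principal_axis_length_1_mm
morph.principal_axis_length_2_mm
morph.principal_axis_length_3_mm
morph.convex_volume_mm3
morph.solidity
morph.surface_area_mm2
firstorder.mean
firstorder.median
firstorder.std
firstorder.variance
firstorder.minimum
firstorder.maximum
firstorder.p5
firstorder.p25
firstorder.p75
firstorder.p95
firstorder.kurtosis
firstorder.skewness
glcm.energy.d8_o01
glcm.energy.d8_o02
glcm.energy.d8_o03
glcm.energy.d8_o04
glcm.energy.d8_o05
glcm.energy.d8_o06
glcm.energy.d8_o07
glcm.energy.d8_o08
glcm.energy.d8_o09
glcm.energy.d8_o10
glcm.energy.d8_o11
glcm.energy.d8_o12
glcm.energy.d8_o13
glcm.entropy.d8_o01
glcm.entropy.d8_o02
glcm.entropy.d8_o03
glcm.entropy.d8_o04
glcm.entropy.d8_o05
glcm.entropy.d8_o06
glcm.entropy.d8_o07
glcm.entropy.d8_o08
glcm.entropy.d8_o09
glcm.entropy.d8_o10
glcm.entropy.d8_o11
glcm.entropy.d8_o12
glcm.entropy.d8_o13
glcm.correlation.d8_o01
glcm.correlation.d8_o02
glcm.correlation.d8_o03
glcm.correlation.d8_o04
glcm.correlation.d8_o05
glcm.correlation.d8_o06
glcm.correlation.d8_o07
glcm.correlation.d8_o08
glcm.correlation.d8_o09
glcm.correlation.d8_o10
glcm.correlation.d8_o11
glcm.correlation.d8_o12
glcm.correlation.d8_o13
glcm.contrast.d8_o01
glcm.contrast.d8_o02
glcm.contrast.d8_o03
glcm.contrast.d8_o04
glcm.contrast.d8_o05
glcm.contrast.d8_o06
glcm.contrast.d8_o07
glcm.contrast.d8_o08
glcm.contrast.d8_o09
glcm.contrast.d8_o10
glcm.contrast.d8_o11
glcm.contrast.d8_o12
glcm.contrast.d8_o13
glcm.variance.d8_o01
glcm.variance.d8_o02
glcm.variance.d8_o03
glcm.variance.d8_o04
glcm.variance.d8_o05
glcm.variance.d8_o06
glcm.variance.d8_o07
glcm.variance.d8_o08
glcm.variance.d8_o09
glcm.variance.d8_o10
glcm.variance.d8_o11
glcm.variance.d8_o12
glcm.variance.d8_o13
glcm.sum_mean.d8_o01
glcm.sum_mean.d8_o02
glcm.sum_mean.d8_o03
glcm.sum_mean.d8_o04
glcm.sum_mean.d8_o05
glcm.sum_mean.d8_o06
glcm.sum_mean.d8_o07
glcm.sum_mean.d8_o08
glcm.sum_mean.d8_o09
glcm.sum_mean.d8_o10
glcm.sum_mean.d8_o11
glcm.sum_mean.d8_o12
glcm.sum_mean.d8_o13
glcm.inertia.d8_o01
glcm.inertia.d8_o02
glcm.inertia.d8_o03
glcm.inertia.d8_o04
glcm.inertia.d8_o05
glcm.inertia.d8_o06
glcm.inertia.d8_o07
glcm.inertia.d8_o08
glcm.inertia.d8_o09
glcm.inertia.d8_o10
glcm.inertia.d8_o11
glcm.inertia.d8_o12
glcm.inertia.d8_o13
glcm.cluster_shade.d8_o01
glcm.cluster_shade.d8_o02
glcm.cluster_shade.d8_o03
glcm.cluster_shade.d8_o04
glcm.cluster_shade.d8_o05
glcm.cluster_shade.d8_o06
glcm.cluster_shade.d8_o07
glcm.cluster_shade.d8_o08
glcm.cluster_shade.d8_o09
glcm.cluster_shade.d8_o10
glcm.cluster_shade.d8_o11
glcm.cluster_shade.d8_o12
glcm.cluster_shade.d8_o13
glcm.cluster_tendency.d8_o01
glcm.cluster_tendency.d8_o02
glcm.cluster_tendency.d8_o03
glcm.cluster_tendency.d8_o04
glcm.cluster_tendency.d8_o05
glcm.cluster_tendency.d8_o06
glcm.cluster_tendency.d8_o07
glcm.cluster_tendency.d8_o08
glcm.cluster_tendency.d8_o09
glcm.cluster_tendency.d8_o10
glcm.cluster_tendency.d8_o11
glcm.cluster_tendency.d8_o12
glcm.cluster_tendency.d8_o13
glcm.homogeneity.d8_o01
glcm.homogeneity.d8_o02
glcm.homogeneity.d8_o03
glcm.homogeneity.d8_o04
glcm.homogeneity.d8_o05
glcm.homogeneity.d8_o06
glcm.homogeneity.d8_o07
glcm.homogeneity.d8_o08
glcm.homogeneity.d8_o09
glcm.homogeneity.d8_o10
glcm.homogeneity.d8_o11
glcm.homogeneity.d8_o12
glcm.homogeneity.d8_o13
glcm.max_probability.d8_o01
glcm.max_probability.d8_o02
glcm.max_probability.d8_o03
glcm.max_probability.d8_o04
glcm.max_probability.d8_o05
glcm.max_probability.d8_o06
glcm.max_probability.d8_o07
glcm.max_probability.d8_o08
glcm.max_probability.d8_o09
glcm.max_probability.d8_o10
glcm.max_probability.d8_o11
glcm.max_probability.d8_o12
glcm.max_probability.d8_o13
glcm.inverse_variance.d8_o01
glcm.inverse_variance.d8_o02
glcm.inverse_variance.d8_o03
glcm.inverse_variance.d8_o04
glcm.inverse_variance.d8_o05
glcm.inverse_variance.d8_o06
glcm.inverse_variance.d8_o07
glcm.inverse_variance.d8_o08
glcm.inverse_variance.d8_o09
glcm.inverse_variance.d8_o10
glcm.inverse_variance.d8_o11
glcm.inverse_variance.d8_o12
glcm.inverse_variance.d8_o13
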