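# SYNTHETIC demo reference model.
#
# These centroid coordinates and scaling parameters are invented for
# demonstrations and tests.  They are clinically plausible caricatures of
# the four type 2 diabetes subtypes (SIDD: insulin-deficient with high
# HbA1c; SIRD: insulin-resistant with high HOMA indices; MOD: young and
# obese; MARD: older with mild metabolic derangement) but are NOT the
# published sex-specific ANDIS centroids.  Enter published centroid
# coordinates through this same schema for real analyses.
variables: [age_at_diagnosis, bmi, hba1c, homa2_b, homa2_ir]
clusters: [SIDD, SIRD, MOD, MARD]
transforms: {}
sexes:
  male:
    scaling:
      age_at_diagnosis: {mean: 56.0, sd: 11.0}
      bmi: {mean: 30.5, sd: 5.5}
      hba1c: {mean: 52.0, sd: 12.0}
      homa2_b: {mean: 85.0, sd: 35.0}
      homa2_ir: {mean: 2.6, sd: 1.3}
    centroids:
      SIDD: [-0.6, -0.6, 1.9, -1.3, -0.3]
      SIRD: [0.5, 0.9, -0.3, 0.9, 1.7]
      MOD: [-1.0, 1.2, -0.1, 0.5, 0.3]
      MARD: [0.9, -0.5, -0.3, -0.1, -0.5]
  female:
    scaling:
      age_at_diagnosis: {mean: 57.0, sd: 11.5}
      bmi: {mean: 31.5, sd: 6.5}
      hba1c: {mean: 51.0, sd: 11.5}
      homa2_b: {mean: 90.0, sd: 38.0}
      homa2_ir: {mean: 2.4, sd: 1.2}
    centroids:
      SIDD: [-0.7, -0.5, 1.8, -1.2, -0.3]
      SIRD: [0.6, 1.0, -0.3, 0.8, 1.6]
      MOD: [-1.1, 1.3, -0.1, 0.5, 0.4]
      MARD: [0.8, -0.6, -0.3, -0.1, -0.4]
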