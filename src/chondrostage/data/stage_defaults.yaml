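# Default per-stage generator parameters for the synthetic chondrocyte
# dedifferentiation model.
#
# ILLUSTRATIVE, NOT MEASURED: these numbers encode only the ordinal
# structure of the biphasic model -- RBP4/SOD3 peak mid-culture (P2),
# IFITM3/F-actin rise monotonically with passage, and cell/nucleus size
# grows -- with magnitudes chosen to look like plausible confocal mean
# gray values (arbitrary units) and cell dimensions (micrometres).
#
# intensity means: arbitrary fluorescence units; cv: coefficient of
# variation of the log-normal intensity model; diameters: micrometres
# (equivalent-circle diameter); size_correlation: cell-nucleus diameter
# correlation; aspect_ratio_max: upper bound of the uniform aspect-ratio
# draw (round -> fibroblast-like elongation with passage).
stages:
  P0:
    rbp4_mean: 40.0
    sod3_mean: 35.0
    ifitm3_mean: 20.0
    factin_mean: 30.0
    rbp4_cv: 0.25
    sod3_cv: 0.25
    ifitm3_cv: 0.25
    factin_cv: 0.25
    cell_diameter_mean: 18.0
    cell_diameter_sd: 2.0
    nucleus_diameter_mean: 8.0
    nucleus_diameter_sd: 0.8
    size_correlation: 0.6
    aspect_ratio_max: 1.6
  P2:
    rbp4_mean: 100.0
    sod3_mean: 90.0
    ifitm3_mean: 35.0
    factin_mean: 45.0
    rbp4_cv: 0.25
    sod3_cv: 0.25
    ifitm3_cv: 0.25
    factin_cv: 0.25
    cell_diameter_mean: 22.0
    cell_diameter_sd: 2.5
    nucleus_diameter_mean: 9.0
    nucleus_diameter_sd: 0.9
    size_correlation: 0.6
    aspect_ratio_max: 1.8
  P4:
    rbp4_mean: 60.0
    sod3_mean: 55.0
    ifitm3_mean: 60.0
    factin_mean: 70.0
    rbp4_cv: 0.25
    sod3_cv: 0.25
    ifitm3_cv: 0.25
    factin_cv: 0.25
    cell_diameter_mean: 28.0
    cell_diameter_sd: 3.0
    nucleus_diameter_mean: 11.0
    nucleus_diameter_sd: 1.1
    size_correlation: 0.6
    aspect_ratio_max: 2.0
  P8:
    rbp4_mean: 35.0
    sod3_mean: 30.0
    ifitm3_mean: 95.0
    factin_mean: 110.0
    rbp4_cv: 0.25
    sod3_cv: 0.25
    ifitm3_cv: 0.25
    factin_cv: 0.25
    cell_diameter_mean: 34.0
    cell_diameter_sd: 3.5
    nucleus_diameter_mean: 13.0
    nucleus_diameter_sd: 1.3
    size_correlation: 0.6
    aspect_ratio_max: 2.2
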