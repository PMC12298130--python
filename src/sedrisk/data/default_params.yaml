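# Default parameter set for the Datong Lake (Dongting basin) sediment assessment.
#
# Units: concentrations and backgrounds in mg/kg dry weight; RfD in mg/(kg day);
# SF in (mg/(kg day))^-1; ABS dimensionless; exposure units noted per row.
# Missing SF entries mean "pathway not evaluated for this element" and are
# skipped downstream, never imputed as zero.

elements: [As, Cd, Cr, Cu, Mn, Ni, Pb, Zn]
reference_element: Al

# Dongting Lake basin sediment background values (DLSHBV), mg/kg.
# The Al background is a crust-scale constant; only the sample/background Al
# ratio matters to the enrichment factor.
background:
  As: 12.90
  Cd: 0.33
  Cr: 44.00
  Cu: 20.20
  Mn: 450.00
  Ni: 21.20
  Pb: 23.30
  Zn: 83.30
  Al: 62600.0

# Hakanson biological toxicity factors (dimensionless).
toxicity_factor:
  As: 10
  Cd: 30
  Cr: 2
  Cu: 5
  Mn: 1
  Ni: 5
  Pb: 5
  Zn: 1

rfd:
  ingestion:
    As: 3.0e-4
    Cd: 1.0e-3
    Cr: 3.0e-3
    Cu: 4.0e-2
    Hg: 3.0e-4
    Ni: 2.0e-2
    Pb: 3.5e-3
    Zn: 0.35
    Mn: 4.6e-2
  dermal:
    As: 1.23e-4
    Cd: 1.0e-5
    Cr: 6.0e-5
    Cu: 1.2e-2
    Hg: 2.1e-5
    Ni: 5.4e-3
    Pb: 5.25e-3
    Zn: 6.0e-2
    Mn: 1.84e-3

# Cancer slope factors; elements absent here have no SF for that pathway.
sf:
  ingestion:
    As: 1.5
    Cd: 1.8
    Cr: 0.5
    Pb: 8.5e-3
  dermal:
    As: 1.5
    Cd: 0.38

# Dermal absorption fraction per element (dimensionless).
abs:
  As: 0.03
  Cd: 0.14
  Cr: 0.001
  Cu: 0.1
  Ni: 0.35
  Pb: 0.006
  Zn: 0.02
  Mn: 0.01

# Exposure parameter distributions per population group.
# ir_ing mg/day; ed years; ef days/year; bw kg; sa m^2 (converted to cm^2
# internally); af mg/(cm^2 day); cf kg/mg.
exposure_profiles:
  adult_male:
    ir_ing: 114
    ed: 70
    ef: {family: triangular, mode: 345, min: 180, max: 365}
    bw: {family: lognormal, mean: 67.55, sd: 8.72}
    sa: {family: triangular, mode: 0.169, min: 0.085, max: 0.422}
    af: {family: lognormal, mean: 0.49, sd: 0.54}
    cf: 1.0e-6
  adult_female:
    ir_ing: 114
    ed: 70
    ef: {family: triangular, mode: 345, min: 180, max: 365}
    bw: {family: lognormal, mean: 57.59, sd: 8.03}
    sa: {family: triangular, mode: 0.153, min: 0.076, max: 0.382}
    af: {family: lognormal, mean: 0.49, sd: 0.54}
    cf: 1.0e-6
  child:
    ir_ing: 200
    ed: 18
    ef: {family: triangular, mode: 345, min: 180, max: 365}
    bw: {family: triangular, mode: 29.30, min: 5.20, max: 56.80}
    sa: {family: triangular, mode: 0.086, min: 0.043, max: 0.216}
    af: {family: lognormal, mean: 0.65, sd: 1.2}
    cf: 1.0e-6

# Observed per-element summary statistics (n = 15 sites) with the best-fit
# distribution family selected by the Anderson-Darling statistic. Zn's
# continuous concentration is carried as a (truncated) normal.
concentration_summary:
  As: {family: gumbel_max, mean: 11.37, sd: 1.13, min: 9.78, max: 14.40, median: 11.40}
  Cd: {family: logistic, mean: 0.66, sd: 0.07, min: 0.54, max: 0.79, median: 0.66}
  Cr: {family: gumbel_min, mean: 107.07, sd: 4.85, min: 96.20, max: 112.42, median: 109.00}
  Cu: {family: gumbel_min, mean: 50.81, sd: 3.98, min: 43.70, max: 55.30, median: 51.90}
  Mn: {family: gumbel_max, mean: 1046.13, sd: 107.80, min: 914.00, max: 1287.00, median: 1010.00}
  Ni: {family: triangular, mean: 57.99, sd: 5.15, min: 49.40, max: 64.20, median: 59.27}
  Pb: {family: logistic, mean: 41.36, sd: 2.51, min: 36.00, max: 46.70, median: 41.38}
  Zn: {family: normal, mean: 142.67, sd: 6.44, min: 128.00, max: 151.00, median: 143.00}

n_samples: 15

# Sample-to-background Al concentration ratio used for the enrichment factor
# when no Al column is measured; back-solved so that (mean_i/background_i)/ratio
# reproduces the reported mean EF of every element simultaneously.
al_enrichment_ratio: 1.8727

# Element subset summed into the composite potential ecological risk index RI.
ri_elements: [As, Cd, Cr, Cu, Pb, Zn]
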