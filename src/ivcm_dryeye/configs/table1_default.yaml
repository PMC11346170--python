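# Default synthetic-cohort configuration.
#
# Matches the published dry-eye cohort: 214 eyes of 214 patients
# (63 autoimmune / 151 non-autoimmune), group-level mean +/- SD marginals
# for the clinical variables and grading subscores, and the rank
# correlations reported as significant.  All unreported variable pairs are
# left independent on the latent scale.
#
# Units: age in years, OSDI scales as printed, Schirmer in mm/5min,
# TBUT in seconds, Oxford grade 0-5, pain 0-10, HLA-DR in arbitrary units
# of fluorescence (AUF).
name: table1_default
thresholds:
  tortuosity: 1.2     # arc/chord ratio above which morphology is graded tortuous
  reflectivity: 2.5   # nerve/background intensity ratio graded hyper-reflective
calibration:
  n_calib: 50000      # pairs simulated per bisection step
  seed: 20817         # internal seed of the (deterministic) calibration step
  tol: 0.02           # |achieved - target| Spearman tolerance
latents:
  nerve_density_sigma: 0.5   # log-scale shape of the nerve-density marginal
  tortuosity_sigma: 0.5      # log-scale shape of (tortuosity - 1)
  reflectivity_sigma: 0.3    # log-scale shape of the reflectivity index
  mean_nerve_span_mm: 0.4    # mean traced length of one nerve crossing a frame
groups:
  AIDED:
    n: 63
    female_fraction: 0.97
    clinical:
      age:           {mean: 57,    sd: 12,    family: truncnorm, lo: 18}
      osdi_symptoms: {mean: 13,    sd: 3.6,   family: truncnorm, lo: 0}
      osdi_vision:   {mean: 9,     sd: 4.3,   family: truncnorm, lo: 0}
      osdi_triggers: {mean: 8.4,   sd: 3.8,   family: truncnorm, lo: 0}
      osdi_total:    {mean: 67,    sd: 19,    family: truncnorm, lo: 0, hi: 100}
      oxford:        {mean: 1.7,   sd: 1.5,   family: ordinal, values: [0, 1, 2, 3, 4, 5]}
      schirmer_mm:   {mean: 9.7,   sd: 9.8,   family: lognorm}
      tbut_s:        {mean: 4.2,   sd: 2.7,   family: lognorm}
      pain:          {mean: 4.0,   sd: 2.5,   family: truncnorm, lo: 0, hi: 10}
      hla_dr_auf:    {mean: 72000, sd: 62000, family: lognorm}
    scores:
      icsc_mean: 1.7
      icsc_sd: 0.6
      ndsc_mean: 0.4
      nmsc_mean: 1.4
    targets:
      pairwise:
        - [icsc, hla_dr_auf, 0.4]
        - [ndsc, tbut_s, -0.2]
        - [ndsc, age, 0.2]
        - [icsc, osdi_symptoms, 0.2]
        - [icsc, osdi_vision, 0.2]
        - [schirmer_mm, tbut_s, 0.4]
        - [oxford, schirmer_mm, -0.34]
        - [oxford, tbut_s, -0.3]
        - [osdi_total, oxford, 0.2]
        - [osdi_total, tbut_s, -0.3]
      composite:
        tivcm_hla: 0.25
        nmsc_oxford: 0.3
        nmsc_age: 0.2
  NAIDED:
    n: 151
    female_fraction: 0.68
    clinical:
      age:           {mean: 55,    sd: 15,    family: truncnorm, lo: 18}
      osdi_symptoms: {mean: 11,    sd: 5,     family: truncnorm, lo: 0}
      osdi_vision:   {mean: 7.4,   sd: 4.8,   family: truncnorm, lo: 0}
      osdi_triggers: {mean: 7.3,   sd: 3.9,   family: truncnorm, lo: 0}
      osdi_total:    {mean: 56,    sd: 24,    family: truncnorm, lo: 0, hi: 100}
      oxford:        {mean: 0.8,   sd: 1.1,   family: ordinal, values: [0, 1, 2, 3, 4, 5]}
      schirmer_mm:   {mean: 17,    sd: 10,    family: lognorm}
      tbut_s:        {mean: 6.4,   sd: 3.7,   family: lognorm}
      pain:          {mean: 4.0,   sd: 2.5,   family: truncnorm, lo: 0, hi: 10}
      hla_dr_auf:    {mean: 70000, sd: 66000, family: lognorm}
    scores:
      icsc_mean: 1.7
      icsc_sd: 0.7
      ndsc_mean: 0.4
      nmsc_mean: 1.5
    targets:
      pairwise:
        - [icsc, hla_dr_auf, 0.3]
        - [ndsc, schirmer_mm, -0.24]
        - [ndsc, age, 0.2]
        - [icsc, osdi_symptoms, 0.2]
        - [icsc, osdi_vision, 0.2]
        - [schirmer_mm, tbut_s, 0.4]
        - [oxford, schirmer_mm, -0.34]
        - [oxford, tbut_s, -0.3]
        - [osdi_total, oxford, 0.2]
        - [osdi_total, tbut_s, -0.3]
      composite:
        tivcm_hla: 0.32
        nmsc_oxford: 0.0
        nmsc_age: 0.2
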