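# Default study conditions for the part-solid nodule phantom workflow.
# Lengths in micrometres unless suffixed otherwise; HU dimensionless.

printer:
  spot_um: 85            # SLA laser spot size; all design lengths are multiples

design_grid:
  beam_thicknesses_um: [340, 510, 680]
  void_lengths_um: [680, 850, 1020, 1360, 1700, 2040]

# Four HU classes tiling (-750, +inf); HU below -750 is background (air-like lung).
hu_classes:
  - {name: core, lower: 0.0,    upper: .inf,  lower_inclusive: false, upper_inclusive: false}
  - {name: gg1,  lower: -300.0, upper: 0.0,   lower_inclusive: false, upper_inclusive: true}
  - {name: gg2,  lower: -500.0, upper: -300.0, lower_inclusive: false, upper_inclusive: true}
  - {name: gg3,  lower: -750.0, upper: -500.0, lower_inclusive: true,  upper_inclusive: true}

partial_volume:
  hu_air: -1000.0
  # Measured HU extremes of the printed calibration cubes: the densest design
  # (680/680, fill 0.5) read -141 HU, the sparsest (340/2040, fill 0.0554)
  # read -915 HU. The default effective material HU is least-squares fitted
  # through these anchors (about +716 HU).
  calibration_anchors:
    - {t_um: 680, g_um: 680,  mean_hu: -141.0}
    - {t_um: 340, g_um: 2040, mean_hu: -915.0}

# Designs whose periodic print pattern shows on CT (inflating ROI SD) are
# excluded from density selection. Anchors for 340 and 680 come from scanned
# cubes; 510 uses the conservative neighbouring threshold.
visibility_rules:
  - {t_um: 340, g_min_visible_um: 1700, kernel_scope: hard}
  - {t_um: 510, g_min_visible_um: 1020, kernel_scope: hard}
  - {t_um: 680, g_min_visible_um: 1020, kernel_scope: both}

# Designs observed to print defectively and therefore never selected.
defect_exclusions:
  - {t_um: 340, g_um: 680, reason: inhomogeneous material distribution}
  - {t_um: 510, g_um: 680, reason: inhomogeneous material distribution}
  - {t_um: 340, g_um: 850, reason: air gaps where resin is absent}

virtual_ct:
  psf_sigma_mm: 0.6      # isotropic Gaussian PSF, order of clinical CT resolution
  noise_sd_hu: 0.0

visibility_score:
  threshold: 0.2         # coefficient-of-variation + spectral-peak score cutoff

cost:
  resin_price_eur_per_ml: 0.16
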