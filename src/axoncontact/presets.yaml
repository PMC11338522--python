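# Versioned simulation presets.
#
# Each named preset resolves to a complete parameter set for one family of
# synthetic experiments.  Scale factors encode the programmed effect sizes
# that the quantifiers are expected to recover; geometry, photon budgets and
# noise levels are simulator conventions (see docs/methods.md).
version: 1
presets:

  # Knockdown of ER tubule-shaping proteins: reduced axonal puromycin
  # (nascent-protein) labeling.  Programmed as a 29% drop in signal photons.
  fig1-kd-puro:
    kind: condition_pair
    scale_factor: 0.71
    scale_target: photon_scale
    length_um: 40.0
    width_nm: 600.0
    n_puncta: 300
    amplitude_cv: 0.3
    er_tubule_radius_nm: 50.0
    bound_fraction: 0.0
    bind_distance_nm: 0.0
    pixel_size_nm: 80.0
    psf_fwhm_nm: 250.0
    photon_scale: 150.0
    read_noise_sd: 2.0
    background_level: 20.0
    n_replicates: 30

  # Motor-driven removal of the axonal ER: 30% drop in puromycin labeling.
  fig1-removal-puro:
    kind: condition_pair
    scale_factor: 0.70
    scale_target: photon_scale
    length_um: 40.0
    width_nm: 600.0
    n_puncta: 300
    amplitude_cv: 0.3
    er_tubule_radius_nm: 50.0
    bound_fraction: 0.0
    bind_distance_nm: 0.0
    pixel_size_nm: 80.0
    psf_fwhm_nm: 250.0
    photon_scale: 150.0
    read_noise_sd: 2.0
    background_level: 20.0
    n_replicates: 30

  # Same knockdown, ribosomal-protein (RpS12) channel: 37% fewer ribosome
  # puncta, programmed as a density reduction rather than a photon reduction.
  fig1-kd-rps12:
    kind: condition_pair
    scale_factor: 0.63
    scale_target: density
    length_um: 40.0
    width_nm: 600.0
    n_puncta: 500
    amplitude_cv: 0.3
    er_tubule_radius_nm: 50.0
    bound_fraction: 0.0
    bind_distance_nm: 0.0
    pixel_size_nm: 80.0
    psf_fwhm_nm: 250.0
    photon_scale: 150.0
    read_noise_sd: 2.0
    background_level: 20.0
    n_replicates: 30

  # Null control: identical groups, for calibrating the comparison machinery.
  null-pair:
    kind: condition_pair
    scale_factor: 1.0
    scale_target: photon_scale
    length_um: 40.0
    width_nm: 600.0
    n_puncta: 300
    amplitude_cv: 0.3
    er_tubule_radius_nm: 50.0
    bound_fraction: 0.0
    bind_distance_nm: 0.0
    pixel_size_nm: 80.0
    psf_fwhm_nm: 250.0
    photon_scale: 150.0
    read_noise_sd: 2.0
    background_level: 20.0
    n_replicates: 30

  # STED-like two-channel contact experiment: 45% of ribosome puncta bound
  # within 30 nm of the ER tubule surface, imaged at 60 nm FWHM / 20 nm px.
  fig2-sted-contact:
    kind: contact
    length_um: 30.0
    width_nm: 460.0
    n_puncta: 240
    amplitude_cv: 0.25
    bound_fraction: 0.45
    bind_distance_nm: 30.0
    er_tubule_radius_nm: 75.0
    pixel_size_nm: 20.0
    psf_fwhm_nm: 60.0
    photon_scale: 2500.0
    photon_scale_er: 10.0
    read_noise_sd: 1.0
    background_level: 0.1
    dilate_nm: 5.0
    n_replicates: 20

  # Split-APEX proximity labeling along branched axons: punctum linear
  # density inside branch-point windows is 1.75x the shaft density.
  fig3-branch:
    kind: branch
    length_um: 40.0
    width_nm: 600.0
    n_branches: 3
    branch_window_um: 2.0
    shaft_density_per_um: 12.0
    branch_enrichment: 1.75
    amplitude_cv: 0.3
    pixel_size_nm: 80.0
    psf_fwhm_nm: 250.0
    photon_scale: 150.0
    read_noise_sd: 2.0
    background_level: 20.0
    n_replicates: 16
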