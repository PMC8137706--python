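# Default synthetic-cohort calibration.
#
# Peak locations/values and variance hotspot levels follow the printed
# surface statistics of the study cohort this generator emulates
# (normal middle ears vs ears with otitis media with effusion).
# Bump widths are this package's own choice: narrow enough that each
# class-mean peak is a well-defined single maximum at grid resolution.
# Peak amplitudes are solved at load time so the summed template attains
# each listed `value` exactly at its (freq_hz, press_dapa) centre.
normal:
  baseline: 0.10
  peaks:
    - {freq_hz: 820, press_dapa: 0, width_logf: 0.30, width_press: 40, value: 0.39}
    - {freq_hz: 1335, press_dapa: 20, width_logf: 0.25, width_press: 40, value: 0.50}
    - {freq_hz: 3270, press_dapa: 65, width_logf: 0.35, width_press: 55, value: 0.76}
  variance:
    baseline: 0.012
    hotspots:
      - {freq_hz: 2085, press_dapa: -205, width_logf: 0.25, width_press: 80, level: 0.058}
      - {freq_hz: 5339, press_dapa: -10, width_logf: 0.15, width_press: 30, level: 0.058}
ome:
  baseline: 0.15
  peaks:
    - {freq_hz: 5000, press_dapa: -30, width_logf: 0.25, width_press: 50, value: 0.50}
  variance:
    baseline: 0.015
    hotspots:
      - {freq_hz: 4511, press_dapa: 120, width_logf: 0.30, width_press: 70, level: 0.095}
n_normal: 423
n_ome: 249
pressure_dropout: 0.15
pressure_jitter: 3.0
noise_blur_sigma: 0.0
seed: 20210520
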