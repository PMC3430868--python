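# Default effect configuration for the synthetic telemetry generator.
#
# Percent effects are the values reported by the vaginal-distention VMR
# telemetry study this package models.  Everything else (absolute threshold
# scale, noise magnitudes, the 5 mg/kg effect) is a free parameter of the
# generator, not a reported quantity.

reference_threshold: 0.5   # ml, shamENDO mean; free parameter (scale only)
max_volume: 1.0            # ml, ramp cap (reported protocol)

endo_proestrus_reduction: 42.4   # % ENDO proestrus below shamENDO (reported)
stage_reductions:                # % ENDO proestrus below each other stage;
  DI: 15.0                       # reported as a 15-19% band, endpoints fixed
  DII: 17.0                      # so both band edges are recoverable
  E: 19.0
sham_stage_effect: 0.0           # shamENDO showed no estrous-stage effect

drug_effects:                    # % threshold increase over untreated mean
  - {group: ENDO, treatment: indomethacin, dose: 10, route: ip, percent: 81.0}
  - {group: ENDO, treatment: indomethacin, dose: 10, route: sc, percent: 93.5}
  - {group: ENDO, treatment: indomethacin, dose: 5, route: ip, percent: 40.0}  # free: study reports direction only
  - {group: ENDO, treatment: vehicle, dose: 0, route: ip, percent: 28.0}       # injection effect
  - {group: ENDO, treatment: vehicle, dose: 0, route: sc, percent: 0.0}

rat_cv: 0.15        # between-rat CV of the persistent random effect (free)
session_cv: 0.08    # within-rat between-session CV (free)
vmr_gain: 6.0       # EMG amplitude multiple once threshold crossed (free;
                    # must exceed the 2.0 detection ratio with enough margin
                    # that single 100 ms bins rarely dip below criterion)

noise:              # resting-EMG model (free parameters)
  amplitude_uv: 25.0
  burst_rate_hz: 60.0
  burst_height: 0.4
  burst_tau_s: 0.03
  floor: 1.0
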