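# Default synthetic burn scenario, v1.
#
# Class/time-conditional targets for the hemoglobin indices of the three
# burn-severity classes (1 = 70C superficial dermal, 2 = 78C deep dermal,
# 3 = 98C deep) at 5 min, 24 h, 48 h and 72 h post-burn.  These values are a
# QUALITATIVE emulation of the reported severity-dependent trajectories
# (superficial burns: hyperaemic CHbT rise and only a transient StMet peak;
# deeper burns: depressed CHbT and persistently rising StMet); the source
# protocol prints no numeric field values, so the numbers below are package
# defaults, not measurements.
version: "1"
class_means:
  1:
    chbt:  [10.0, 14.0, 16.0, 18.0]
    sto2:  [60.0, 45.0, 55.0, 60.0]
    stmet: [ 6.0, 10.0,  3.0,  2.0]
  2:
    chbt:  [ 8.0,  6.0,  5.0,  5.0]
    sto2:  [45.0, 35.0, 50.0, 55.0]
    stmet: [ 8.0, 15.0, 22.0, 28.0]
  3:
    chbt:  [ 6.0,  4.0,  3.5,  3.0]
    sto2:  [40.0, 30.0, 45.0, 50.0]
    stmet: [12.0, 25.0, 35.0, 45.0]
subject_sd:      {chbt: 1.5, sto2: 5.0, stmet: 3.0}
field_sd:        {chbt: 1.0, sto2: 4.0, stmet: 2.5}
correlation_length_px: 8.0
sensor_noise_sd: 0.005
image_shape: [128, 128]
time_points_s: [300.0, 86400.0, 172800.0, 259200.0]
subjects_per_class: 7
test_subjects_per_class: 4
cm_mean: 0.0
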