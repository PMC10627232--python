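# Example phantom configuration for `seqrubric simulate --config ...`
# Any omitted key falls back to the package default (64x64x40 grid at
# 1 mm, four sequences, 5 subjects, 5 observers).

shape: [48, 48, 32]
spacing_mm: [1.25, 1.25, 1.5]
n_subjects: 5
n_observers: 5

# Observer contour jitter: signed boundary morph radius ~ N(0, sd) in mm
# and an independent translation ~ N(0, sd) per axis.
jitter_radius_sd_mm: 1.0
jitter_translation_sd_mm: 0.5

# One entry per simulated sequence.  structure_means are mean signal
# intensities per organ (sides share a mean); fat_factor scales the
# unsuppressed fat mean (1.0 = no suppression); noise_sd is the SD of
# the additive Gaussian noise.
sequences:
  - sequence_id: nonfs
    structure_means: {GTV: 60, lymph_nodes: 55, parotid: 45, pterygoid: 70}
    fat_factor: 1.0
    noise_sd: 6.0
  - sequence_id: spair1
    structure_means: {GTV: 65, lymph_nodes: 60, parotid: 55, pterygoid: 50}
    fat_factor: 0.04
    noise_sd: 7.0
  - sequence_id: spair4
    structure_means: {GTV: 70, lymph_nodes: 65, parotid: 60, pterygoid: 50}
    fat_factor: 0.05
    noise_sd: 6.0

# Per-sequence (p_positive, p_neutral, p_negative) comment probabilities
# for the simulated qualitative feedback.
favorability:
  nonfs: [0.15, 0.55, 0.30]
  spair1: [0.35, 0.50, 0.15]
  spair4: [0.40, 0.50, 0.10]
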