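# Example run configuration (every key shown with its default).
# Unknown keys are rejected at load time; all sections are optional.

seed: 1
output_dir: runs/out

optics:
  wavelength: 690.0          # emission wavelength (nm)
  na: 1.35                   # numerical aperture
  n_immersion: 1.406         # immersion-medium refractive index
  n_sample: 1.35             # sample-medium refractive index
  pixel_size: 119.0          # camera pixel pitch at the sample plane (nm)
  pupil_grid: 64             # pupil samples per side (FFT size)
  psf_size: 32               # rendered image side (pixels)
  plane_offsets: [-300.0, 300.0]   # biplane detection offsets (nm)

basis:
  n_modes: 6                 # mirror modes (28 for the full-scale setup)
  first_mode: 4              # first Wyant index (4 = oblique astigmatism)
  coupling_strength: 0.1     # mirror cross-coupling scale
  seed: 7

acquisition:
  frame_size: 128            # pixels per side
  mean_emitters: 13.0        # expected emitters per frame (Poisson)
  z_range: [-1000.0, 1000.0] # axial positions (nm, uniform)
  mean_photons: 2500.0       # per-emitter photons (exponential mean)
  background: 10.0           # background photons per pixel
  frames_per_cycle: 20
  photon_threshold: 1500.0   # minimum subregion photons
  subregion_size: 32
  isolation_radius: 16.0
  detect_sigma: 1.0
  detect_threshold: 12.0

training:
  warm_start: true           # wider-range networks start from the previous one
  photon_range: [1000.0, 8000.0]
  background_range: [2.0, 20.0]
  z_range: [-1000.0, 1000.0]
  subregion_size: 32
  seed: 0
  networks:
    - amplitude_range: [0.0, 0.8]
      n_samples: 13000
      epochs: 24
    - amplitude_range: [0.0, 1.8]
      n_samples: 8000
      epochs: 16
      lr: 0.002
      reinforce_range: [0.9, 1.8]
      reinforce_samples: 6000
    - amplitude_range: [0.0, 3.0]
      n_samples: 6000
      epochs: 16
      lr: 0.002
      reinforce_range: [1.5, 3.0]
      reinforce_samples: 5000

loop:
  max_updates: 20
  frames_per_cycle: 50
  frames_chunk: 10
  gain: 1.0
  stop_threshold: 0.1        # posterior W_rms to declare convergence (rad)
  stop_consecutive: 2
  max_subregions: 40
  focal_shift_constants: {}  # e.g. {5: -0.3, 15: -0.2} um per unit amplitude
  mirror_stroke: 4.0         # tanh saturation scale (rad/mode)
  mirror_response_gain: 1.0
  mirror_actuation_noise: 0.0

metric_ao:
  n_amplitudes: 11
  amplitude_span: [-1.0, 1.0]
  n_iterations: 5
  mask_sigma: 2.0
  fit_window: 5
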