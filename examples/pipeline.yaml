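# Full-pipeline config: simulate the widening-gap scenario, build the index,
# compute moving-window life tables and the gap trend, write all outputs.
out_dir: scratch/pipeline-demo
years: [2003, 2022]
window: 3
scenario:
  n_areas: 400
  years: [2003, 2022]
  pop_scale: 200000
  pop_dispersion: 0.8
  hazard_params:
    female: {makeham_c: 1.0e-4, gompertz_a: 7.43e-6, gompertz_b: 0.11}
    male: {makeham_c: 2.0e-4, gompertz_a: 3.67e-5, gompertz_b: 0.095}
  gradient_gamma: {female: 0.0450, male: 0.0864}
  drift_per_year: {female: 0.99122, male: 0.98874}
  drift_gradient: {female: 0.00181, male: 0.00139}
  indicator_noise_sd: 0.5
  seed: 20030
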