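# pacpredict

Phase–amplitude coupling (PAC) and band-spectral features for
interictal-vs-preictal scalp-EEG classification, with a
seizure-prediction-horizon (SPH) sweep.

The pipeline:

1. **synthetic** — generate long annotated multichannel EEG-like recordings
   with controllable, state-dependent theta/beta→gamma coupling (weak in
   interictal stretches, strong and bursty before each seizure onset), over
   white or pink background noise.
2. **edf** — a minimal 16-bit EDF reader/writer plus seizure-annotation
   sidecars (two-column CSV or CHB-MIT-style plain-text summaries) and a
   JSON cohort manifest.
3. **preprocess** — zero-phase notch (Q=30) and 5th-order Butterworth
   band decomposition into the canonical delta/theta/alpha/beta/gamma bands,
   with a pass-through ICA hook.
4. **segmentation** — SPH/preictal/ictal state labeling around annotated
   (lead-merged) seizures, 30-s windows with 15-s step, postictal guard,
   and seeded interictal/preictal class balancing.
5. **features** — modulation index per (phase band, amplitude band) pair
   (18 phase bins of 20°, KL-to-uniform normalized by log N) and Welch
   peak/median frequency per band, per window and channel.
6. **classify** — max–min normalization to (−1, 1) fitted on training rows,
   grouped 10-fold cross-validation (one seizure's windows never straddle
   folds), random-forest grid search, and accuracy/precision/recall/F1 with
   preictal as the positive class.
7. **sweep** — rerun the pipeline at SPH ∈ {5, 10, 15} min and compare
   per-recording accuracies with a tie-corrected Kruskal–Wallis test.

## CLI

One entry point with subcommands:

```bash
pacpredict synth   --config cfg.json --out rec.edf      # EDF + annotations CSV
pacpredict inspect rec.edf --annotations rec.annotations.csv
pacpredict segment rec.edf --annotations rec.annotations.csv --sph 5 --out windows.csv
pacpredict features rec.edf --windows windows.csv --set both --out features.csv
pacpredict classify features.csv --k 10 --seed 7 --out report.json
pacpredict sweep   --config cfg.json --out sweep.json
pacpredict run     --config cfg.json --out-dir out/     # full chain + manifest
```

The run config is a single JSON (or YAML) file with per-module sections
(`synthetic`, `segmentation`, `features`, `classifier`, optional `sweep`)
and a top-level `seed`; see `tests/test_cli.py::base_config` for a complete
example.  Reruns with the same config reproduce every artifact bit-for-bit.

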