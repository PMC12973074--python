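"""Generate and store one synthetic EEG-fMRI session.

Writes the HDF5 signal container, the BIDS-style events table and the
ground-truth record to --out, then prints a short acquisition summary and
the per-run noise-ceiling correlations (the oracle any decoder is judged
against).

Usage:
    python analysis/01_simulate_session.py --seed 0 --out results/session [--full-scale]
"""

import argparse
from pathlib import Path

import numpy as np

from eeg2bold.synth import SyntheticConfig, oracle_envelope_r, simulate_session, write_session
from eeg2bold.workbench import desk_scale_config


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/session"))
    ap.add_argument("--full-scale", action="store_true",
                    help="62 channels, 4 runs x 530 volumes (the emulated "
                         "acquisition); default is the desk-scale profile")
    args = ap.parse_args()

    if args.full_scale:
        cfg = SyntheticConfig(seed=args.seed)
    else:
        cfg = desk_scale_config(args.seed).synthetic
    runs, bolds, events, truth = simulate_session(cfg)
    write_session(args.out, runs, bolds, events, truth)

    print(f"session: {cfg.n_runs} runs x {cfg.volumes_per_run} volumes "
          f"(TR {cfg.tr_s} s), {cfg.n_channels}-channel EEG at {cfg.fs_hz:g} Hz")
    print(f"events: {cfg.trials_per_run} trials/run, feedback at +5 s, "
          f"win/loss balanced")
    ceilings = [oracle_envelope_r(truth, b) for b in bolds["VS"]]
    print("noise ceiling (oracle r) per run:",
          " ".join(f"{r:.3f}" for r in ceilings),
          f"| mean {np.mean(ceilings):.3f}")
    print(f"written to {args.out}/")


if __name__ == "__main__":
    main()
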