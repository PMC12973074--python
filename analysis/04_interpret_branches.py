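"""Spatio-spectral read-out of a trained experiment bundle.

Loads the fold checkpoints written by 02_train_and_validate.py, re-runs the
ablation ranking on each fold's held-out run and prints the rank-averaged
top-branch profiles: peak frequency and, when the generating ground truth
is available (same seed), the cosine similarity between the recovered
spatial pattern and the planted source pattern.

Usage:
    python analysis/04_interpret_branches.py --bundle results/experiment --seed 0
"""

import argparse
from pathlib import Path

from eeg2bold.interpret import top_branches_report
from eeg2bold.model import load_checkpoint
from eeg2bold.workbench import config_from_yaml, prepare_session


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", type=Path, default=Path("results/experiment"))
    ap.add_argument("--k", type=int, default=3)
    args = ap.parse_args()

    cfg = config_from_yaml((args.bundle / "config.yaml").read_text())
    session = prepare_session(cfg)

    checkpoints = sorted(
        args.bundle.glob("fold*_model.npz"),
        key=lambda p: int(p.stem.removeprefix("fold").removesuffix("_model")),
    )
    models = [load_checkpoint(path) for path in checkpoints]

    # the fold split is a pure function of the config seed, so the held-out
    # run of each checkpoint can be reconstructed exactly
    from eeg2bold.training import make_folds
    from eeg2bold.workbench import _STAGE_FOLDS, _stage_seed

    folds = make_folds([r.run_id for r in session.runs], len(models),
                       _stage_seed(cfg.global_seed, _STAGE_FOLDS))
    pairs = [session.pairs[f.test_run] for f in folds]

    profiles = top_branches_report(models, pairs, cfg.train.window_s,
                                   k=min(args.k, cfg.model.n_branches))
    truth_pattern = None
    if session.truth is not None:
        truth_pattern = session.truth.patterns[0]
        planted = float(session.truth.center_freqs_hz[0])
        print(f"planted source: {planted:g} Hz")
    for rank, prof in enumerate(profiles, start=1):
        line = (f"rank {rank}: importance (delta r) = {prof.importance:.3f}, "
                f"peak frequency = {prof.peak_freq_hz:.1f} Hz")
        if truth_pattern is not None:
            cos = abs(float(prof.spatial_pattern @ truth_pattern))
            line += f", |cos(pattern, planted)| = {cos:.3f}"
        print(line)


if __name__ == "__main__":
    main()
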