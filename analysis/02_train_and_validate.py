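"""Run the full cross-validated translation experiment.

Simulates a desk-scale session, trains the convolutional autoencoder and
the ridge band-power baseline on identical run-level folds, evaluates every
held-out run (Pearson r, phase-randomization p, native-rate control,
win/loss betas, control-ROI correlations), runs the group-level paired
tests and writes the complete bundle (per-fold TSV/JSON, checkpoints,
group report, figures) under --out.

Usage:
    python analysis/02_train_and_validate.py --seed 0 --out results/experiment --folds 4
"""

import argparse
import logging
from pathlib import Path

from eeg2bold.workbench import desk_scale_config, run_experiment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/experiment"))
    ap.add_argument("--folds", type=int, default=4)
    ap.add_argument("--runs", type=int, default=6)
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")

    cfg = desk_scale_config(args.seed, output_dir=str(args.out),
                            n_runs=args.runs, n_folds=args.folds)
    result = run_experiment(cfg)
    rep = result.report

    dl, lin = rep.summary["dl_r"], rep.summary["linear_r"]
    print(f"\nheld-out performance over {rep.n_folds} folds")
    print(f"  deep model  r = {dl['mean']:.3f} (SD {dl['sd']:.3f}, "
          f"min {dl['min']:.3f}, max {dl['max']:.3f})")
    print(f"  linear      r = {lin['mean']:.3f} (SD {lin['sd']:.3f})")
    t = rep.paired_tests["dl_vs_linear_r"]
    print(f"  paired t({t['df']:.0f}) = {t['t']:.3f}, one-sided p = {t['p']:.4f}")
    for roi in ("VC", "PMC", "STN"):
        key = f"target_vs_{roi}_r"
        if key in rep.paired_tests:
            tt = rep.paired_tests[key]
            print(f"  VS vs {roi}: mean control r = "
                  f"{rep.summary[f'r_{roi}']['mean']:.3f}, "
                  f"t({tt['df']:.0f}) = {tt['t']:.3f}, p = {tt['p']:.4f}")
    bt = rep.paired_tests.get("beta_win_vs_loss")
    if bt:
        print(f"  beta win vs loss: t({bt['df']:.0f}) = {bt['t']:.3f}, "
              f"one-sided p = {bt['p']:.4f}")
    print(f"bundle written to {args.out}/")


if __name__ == "__main__":
    main()
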