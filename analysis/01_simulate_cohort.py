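#!/usr/bin/env python
"""Simulate a cohort of synthetic observers on the standard task design.

Each observer runs the full 567-trial session (167 no-stimulus, 90 + 243
low-contrast trials on the 2/1 and 4/1 staircases, 67 high-contrast) with
estimation responses generated by the prior-lapse Bayesian observer
(BAYES_P). Writes one session CSV per observer plus the trial schedule
and a manifest under scratch/sessions/ (bulky regenerable data), and the
run configuration under results/.
"""

from pathlib import Path

from motionprior.pipeline import RunConfig, run_simulate

REPO = Path(__file__).resolve().parent.parent
OUT = REPO / "scratch" / "sessions"
N_OBSERVERS = 12
SEED = 20240901


def main() -> None:
    cfg = RunConfig(seed=SEED, n_observers=N_OBSERVERS)
    OUT.mkdir(parents=True, exist_ok=True)
    (REPO / "results").mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(REPO / "results" / "run_config.yaml")
    paths = run_simulate(cfg, OUT)
    print(f"simulated {len(paths)} sessions "
          f"({cfg.observers[0]['variant']} observer, seed {SEED}) -> {OUT}")


if __name__ == "__main__":
    main()
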