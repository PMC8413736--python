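"""Optional verification against a locally provided trial-level deposit.

The study's raw data are archived externally; this driver is for anyone who
has downloaded that deposit (or any other real child-ANT trial table) and
wants to push it through the exact same pipeline as the synthetic cohorts.
It is deliberately separate from the desk-scale analyses: nothing else in
this repository depends on external data.

Usage:
    python analysis/06_verify_deposit.py --trials path/to/trials.csv \
        [--map subj=participant_id --map RT=rt_ms ...]
"""

import argparse
from pathlib import Path

from antnet.io import TrialTableDialect
from antnet.pipeline import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--trials", required=True, help="trial-level CSV (one row per trial)")
    ap.add_argument(
        "--map",
        action="append",
        default=[],
        metavar="SRC=DEST",
        help="rename a deposit column to the canonical name (repeatable)",
    )
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n-perm", type=int, default=1000)
    ap.add_argument("--out", default=str(ROOT / "scratch" / "deposit_run"))
    args = ap.parse_args()

    column_map = dict(pair.split("=", 1) for pair in args.map)
    dialect = TrialTableDialect(column_map=column_map)
    cfg = RunConfig(seed=args.seed, n_permutations=args.n_perm, out_dir=args.out)
    bundle = run_pipeline(cfg, trials_path=args.trials, dialect=dialect)
    print((Path(args.out) / "report.txt").read_text())


if __name__ == "__main__":
    main()
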