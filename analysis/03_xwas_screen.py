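"""TWAS-style association screen of every scenario feature against its
traits, with Bonferroni control over unique features.

Uses the generating truth weights (the screen's behaviour under perfectly
known cis architecture); the trained-weight comparison lives in
02_train_weights.py.
"""

from pathlib import Path

import pandas as pd

from coloxwas import io_formats as iof
from coloxwas.synthetic import SCENARIO_NAMES, ScenarioSpec, make_scenario
from coloxwas.xwas_assoc import classify_shared, run_xwas_screen

BASE_SEED = 20_240_101
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    all_rows = []
    for i, name in enumerate(SCENARIO_NAMES):
        bundle = make_scenario(ScenarioSpec(name=name, seed=BASE_SEED + i))
        if not bundle.models:
            print(f"{name:18s} no weight models (null scenario)")
            continue
        results = run_xwas_screen(bundle.models, bundle.sumstats,
                                  bundle.panel)
        for r in results:
            all_rows.append({"scenario": name, **r.as_row()})
        n_sig = sum(r.significant for r in results)
        print(f"{name:18s} {len(results)} tests, {n_sig} significant")
        if len(bundle.sumstats) == 2:
            t1, t2 = sorted(bundle.sumstats)
            shared = classify_shared(
                [r for r in results if r.trait_id == t1],
                [r for r in results if r.trait_id == t2])
            n_shared = int((shared["label"] == "shared").sum())
            print(f"{'':18s} shared across {t1}/{t2}: {n_shared} feature(s)")
    df = pd.DataFrame(all_rows)
    iof.write_results_table(df, OUT / "xwas_screen.tsv")
    print(f"\nwrote {len(df)} rows to {OUT / 'xwas_screen.tsv'}")


if __name__ == "__main__":
    main()
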