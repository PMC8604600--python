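"""Demo: descriptive and rank-based comparison of the packaged clinical tables.

The package ships two paired tables (bleeding volume and recovery score,
control vs test group, 40 records each).  The library exposes only
descriptive statistics; this demo additionally runs a Wilcoxon signed-rank
test on the paired columns, as an illustration of how the fixtures can feed
a group comparison.

Usage::

    python scripts/clinical_demo.py
"""

import json

from scipy import stats

from medihash import load_clinical_table, summarize_group


def main() -> None:
    for name in ("bleeding_volume", "recovery"):
        table = load_clinical_table(name)
        control = table.column("control")
        test = table.column("test")
        w = stats.wilcoxon(control, test)
        print(f"== {name} ==")
        for group in ("control", "test"):
            s = {k: round(v, 2) for k, v in summarize_group(table, group).items()}
            print(f"  {group}: {json.dumps(s)}")
        print(f"  wilcoxon signed-rank: W={w.statistic:.1f}, p={w.pvalue:.3g}")


if __name__ == "__main__":
    main()
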