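"""Exclusions and the descriptive demography/fatality table.

Applies the elective / known-status exclusions and 180-day truncation to
the simulated cohort from step 01, then writes the demography table (per
site, complete-case percentages) and the headline fatality figures under
both windowing conventions for the modelled interval.
"""

import json
from pathlib import Path

from fatality_window import (
    apply_exclusions,
    descriptive_table,
    headline_fatality,
    read_cohort_csv,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main() -> None:
    raw = read_cohort_csv(SCRATCH / "cohort.csv")
    table, report = apply_exclusions(raw)
    table.to_csv(SCRATCH / "analysis_table.csv", index=False)

    desc = descriptive_table(table)
    desc.to_csv(RESULTS / "02_descriptive_table.csv", index=False)
    headline = headline_fatality(table)
    payload = {"exclusion_chain": report.to_dict(), "headline": headline}
    (RESULTS / "02_headline.json").write_text(json.dumps(payload, indent=2))

    print("exclusion chain:", report.to_dict())
    print(f"30-day deaths: {headline['dead_0_30']} ({headline['dead_0_30_pct']}%)")
    print(f"90-day deaths: {headline['dead_0_90']} ({headline['dead_0_90_pct']}%)")
    print(f"day 0-2 deaths: {headline['dead_0_2']} ({headline['dead_0_2_pct']}%)")
    print(f"deaths to day 180: {headline['dead_0_180']} ({headline['dead_0_180_pct']}%), "
          f"of which on days 3-180: {headline['dead_3_180']} ({headline['dead_3_180_pct']}%)")


if __name__ == "__main__":
    main()
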