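"""Ingest the raw CSVs, apply exclusions, build the standardized-month table.

Reads the output of 01_simulate_data.py, filters unusable events (missing
date / state / classification / exposure link, off-definition injury
types, recurrent injuries from non-sport mechanisms), classifies states
into the three law-language dichotomies, sums exposures and events into
four-week blocks, and assembles the state x standardized-month analysis
table used by every model downstream.

Writes results/exclusions.json and results/analysis_table.csv.
"""

from pathlib import Path

import lawbend as lb

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"


def main() -> None:
    events, exposures = lb.read_surveillance_csv(
        DATA / "events.csv", DATA / "exposures.csv"
    )
    laws = lb.read_law_csv(DATA / "laws.csv")

    kept, report = lb.apply_exclusions(events)
    report.to_json(ROOT / "exclusions.json")
    print(f"events read: {report.n_input}; kept {report.n_kept}, "
          f"excluded {report.n_excluded} ({100 * report.excluded_fraction:.1f}%)")
    for reason, count in report.reasons.items():
        if count:
            print(f"  {reason}: {count}")

    classification = lb.classify_states(laws)
    sizes = classification.attrs["group_sizes"]
    print("law-language groups:", {k: dict(v) for k, v in sizes.items()})

    blocks = lb.aggregate_four_week(exposures, kept)
    table = lb.build_analysis_table(blocks, laws, classification)
    table.to_csv(ROOT / "analysis_table.csv", index=False)
    dropped = table.attrs["n_dropped_zero_ae"]
    print(f"four-week blocks: {len(blocks)}; analysis cells: {len(table)} "
          f"({dropped} zero-exposure cells dropped)")
    print(f"events conserved into cells: {table['event_count'].sum()} == {report.n_kept}")
    print(f"wrote exclusions.json, analysis_table.csv -> {ROOT}")


if __name__ == "__main__":
    main()
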