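"""Compute the recruitment-effectiveness tables from the fixture.

Reads results/fixture/ (building it if absent) and writes, under
results/effectiveness/: completion rates by method and by city, completion
delays, the demographic cross-tab, and cost per completer with pooled rows.
Prints the headline values.
"""

import runpy
from pathlib import Path

from recruitlag import metrics as mx
from recruitlag.campaign_io import read_cost_ledger, read_participants, write_results

ROOT = Path(__file__).resolve().parents[1]
FIXTURE = ROOT / "results" / "fixture"
OUT = ROOT / "results" / "effectiveness"


def main():
    if not (FIXTURE / "participants.csv").exists():
        runpy.run_path(str(ROOT / "analysis" / "01_build_fixture.py"), run_name="__main__")
    participants = read_participants(FIXTURE / "participants.csv")
    ledger = read_cost_ledger(FIXTURE / "cost_ledger.csv")

    counts = mx.completion_rate(participants, "method_city")
    tables = {
        "completion_by_method": mx.completion_rate(participants, "method"),
        "completion_by_city": mx.completion_rate(participants, "city"),
        "completion_by_mail_group": mx.completion_rate(participants, "mail_group"),
        "delay_by_method": mx.completion_delay(participants, "method"),
        "demographics_by_method": mx.demographic_crosstab(participants),
        "cost_per_completer": mx.cost_per_completer(ledger, counts, hourly_rate=0.0),
    }
    write_results(tables, OUT)

    by_method = tables["completion_by_method"].set_index("method")
    cost = tables["cost_per_completer"]
    pooled = cost[cost.city == "total"].set_index("method")
    print(f"completion rate, mailed letters: {by_method.loc['mailed_letters','completion_rate']:.1f}%")
    print(f"completion rate, snowball:       {by_method.loc['snowball','completion_rate']:.1f}%")
    print(f"cost/completer, social media:    CAD {pooled.loc['social_media','cost_per_completer']:.2f}")
    print(f"cost/completer, partner comms:   CAD {pooled.loc['partner_communications','cost_per_completer']:.2f}")
    print(f"wrote {len(tables)} tables to {OUT}")


if __name__ == "__main__":
    main()
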