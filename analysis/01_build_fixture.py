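"""Enumerate the deterministic participant fixture and its cost ledger.

Writes results/fixture/{participants.csv,cost_ledger.csv}: 2318 recruits
across Montreal, Saskatoon and Vancouver whose city, method, demographic,
participation-option and mail-group margins equal the published study tables
cell by cell, plus a ledger back-solved so each printed cost-per-completer
cell is reproduced.
"""

from pathlib import Path

from recruitlag.campaign_io import write_cost_ledger, write_participants
from recruitlag.synthetic_data import build_fixture

OUT = Path(__file__).resolve().parents[1] / "results" / "fixture"


def main():
    participants, ledger = build_fixture()
    OUT.mkdir(parents=True, exist_ok=True)
    write_participants(participants, OUT / "participants.csv")
    write_cost_ledger(ledger, OUT / "cost_ledger.csv")
    n_comp = int(participants["completer"].sum())
    print(f"fixture: {len(participants)} recruits, {n_comp} completers")
    print(f"wrote {OUT}/participants.csv and {OUT}/cost_ledger.csv")


if __name__ == "__main__":
    main()
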