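"""Simulate one Montreal-like recruitment campaign.

Generates a 199-day campaign schedule (151 paid-reach days, one letter and
reminder campaign, partner/media/snowball/other events), daily recruit
counts from the distributed-lag model at the published coefficients, and
the matching participant table.  Writes results/simulation/.
"""

import argparse
from pathlib import Path

from recruitlag.campaign_io import write_campaign_schedule, write_participants, write_results
from recruitlag.synthetic_data import SimConfig, generate_schedule, simulate_participants, simulate_recruits

OUT = Path(__file__).resolve().parents[1] / "results" / "simulation"


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=11)
    args = parser.parse_args()

    cfg = SimConfig(sigma=2.0)
    schedule = generate_schedule(cfg, seed=args.seed)
    daily = simulate_recruits(schedule, cfg, seed=args.seed + 1)
    participants = simulate_participants(daily, cfg, seed=args.seed + 2)

    OUT.mkdir(parents=True, exist_ok=True)
    write_campaign_schedule(schedule, OUT / "schedule.csv")
    write_results({"recruits": daily}, OUT)
    write_participants(participants, OUT / "participants.csv")
    print(
        f"seed {args.seed}: {int(daily['recruits'].sum())} recruits over {len(schedule)} days "
        f"(mean {daily['recruits'].mean():.2f}/day); wrote {OUT}"
    )


if __name__ == "__main__":
    main()
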