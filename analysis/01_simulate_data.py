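"""Simulate the synthetic surveillance world used by the later steps.

The real state-level surveillance data behind this kind of policy analysis
is restricted-access, so the whole analysis chain here runs on a simulated
world with KNOWN trend structure: 24 states with law-passage dates drawn
from the observed 2009-2014 distribution, a +2%/month pre-law drift, a
-4%/month additional bend one year before passage and a +3%/month partial
rebound one year after, NB2 overdispersion, state-level heterogeneity, and
a little injected missingness so the exclusion filters have work to do.

Writes the raw event, exposure-week and law CSVs under results/data/.
"""

from pathlib import Path

import lawbend as lb

OUT = Path(__file__).resolve().parents[1] / "results" / "data"

CONFIG = lb.SimulationConfig(
    n_states=40,
    stdm_range=(-24, 24),
    beta1=0.02,
    gamma1=-0.04,
    gamma2=0.03,
    tau1=-12,
    tau2=12,
    dispersion=0.3,
    sigma_b=0.35,
    seed=20240917,
    missingness_rates={
        "injury_date": 0.02,
        "state": 0.005,
        "classification": 0.01,
        "nonsport_mechanism": 0.2,
    },
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    CONFIG.to_yaml(OUT / "sim_config.yaml")
    events, exposures, laws = lb.simulate_raw_records(CONFIG)
    lb.write_surveillance_csv(
        events, exposures, OUT / "events.csv", OUT / "exposures.csv"
    )
    lb.write_law_csv(laws, OUT / "laws.csv")
    n_flagged = int(events["_injected_any"].sum())
    print(f"simulated {len(events)} event records across {CONFIG.n_states} states")
    print(f"  ({n_flagged} records carry injected defects for the exclusion filter)")
    print(f"weekly exposure rows: {len(exposures)}")
    print(f"true change points: tau1={CONFIG.tau1}, tau2={CONFIG.tau2} months")
    print(f"wrote events.csv, exposures.csv, laws.csv, sim_config.yaml -> {OUT}")


if __name__ == "__main__":
    main()
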