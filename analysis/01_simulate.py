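"""Simulate the demonstration inpatient registry.

Draws 50,000 synthetic patients (2003–2014 observation window, 1997–2002
washout, 5% washout violators) with three planted comorbidity pairs:
diabetes–CHD (E11–I25, OR 6 in women vs 4 in men), lipid disorders–AMI
(E78–I21, male excess) and nicotine–COPD (F17–J44, sex-neutral), and writes
the stay-level claims CSV plus the generating configuration under scratch/.
"""

from pathlib import Path

from comorbiscan import write_claims
from comorbiscan.synthetic_claims import demo_config, generate

BASE = Path(__file__).resolve().parents[1]
OUT = BASE / "scratch" / "analysis"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = demo_config(n_patients=50_000, seed=20259)
    ds = generate(cfg)
    write_claims(ds, OUT / "claims.csv")
    (OUT / "sim_config.json").write_text(cfg.model_dump_json(indent=2))
    print(f"simulated persons:    {ds.meta['n_simulated']:,}")
    print(f"patients with stays:  {ds.meta['n_patients_emitted']:,}")
    print(f"hospital stays:       {ds.n_stays:,}")
    print(f"claims table:         {OUT / 'claims.csv'}")


if __name__ == "__main__":
    main()
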