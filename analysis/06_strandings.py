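#!/usr/bin/env python
"""Summarize the strandings archive: causes, live/dead trends, composition.

Causes are classified into anthropogenic (bycatch, entanglement, ship
strike, direct killing), non-anthropogenic (disease, poor condition/
starvation, physical trauma), and unknown; yearly counts are explicitly
effort-uncorrected. Prints the composition and the yearly trend table.
"""

from pathlib import Path

from channelfauna import pipeline

HERE = Path(__file__).parent


def main() -> None:
    cfg = pipeline.load_config(HERE / "config.yaml")
    ws = pipeline.simulate(cfg)
    summ = pipeline.run_strandings(cfg, ws)
    print(f"strandings: {summ.n_total}")
    for cat, n in sorted(summ.cause_counts.items()):
        print(f"  {cat}: {n} ({100 * n / summ.n_total:.1f}%)")
    print("\nyearly (effort-uncorrected):")
    print(summ.yearly.to_string())
    print(f"\ntables under {cfg['output_dir']}/strandings/")


if __name__ == "__main__":
    main()
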