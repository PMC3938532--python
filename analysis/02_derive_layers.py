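#!/usr/bin/env python
"""Derive the seasonal predictor stacks and screen them for collinearity.

Seasonal 3-month climatologies of the dynamic fields, Horn-method bottom
slope, Euclidean distance to the 200 m shelf break and to shore, and a
kernel plankton occurrence surface — then the pairwise Pearson screen that
drops the more redundant member of every highly correlated pair (|r| >= 0.7).
Writes every layer and the per-season correlation matrices.
"""

from pathlib import Path

from channelfauna import pipeline
from channelfauna.grids import write_ascii_grid

HERE = Path(__file__).parent


def main() -> None:
    cfg = pipeline.load_config(HERE / "config.yaml")
    ws = pipeline.simulate(cfg)
    ldir = ws.out / "layers"
    ldir.mkdir(parents=True, exist_ok=True)
    for season in cfg["seasons"]:
        screened = pipeline._screen(cfg, ws, season)
        for name, layer in ws.stacks[season].layers.items():
            write_ascii_grid(layer, ldir / f"{name}_{season}.asc")
        dropped = sorted(set(ws.stacks[season].names) - set(screened.names))
        print(f"{season}: kept {screened.names}; dropped {dropped}")
    print(f"correlation matrices in {ldir}/correlation_<season>.csv")


if __name__ == "__main__":
    main()
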