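"""Generate the packaged synthetic reference signature panel.

Writes ``src/clonesoma/data/reference_signatures_synthetic.tsv``: a 96 x 30
matrix in the layout of the COSMIC v2 signature table (one probability
column per signature, canonical 96-class row order).  The profiles are
synthetic — deterministic draws from sparse Dirichlet distributions, with
the first handful shaped after well-known processes (CpG-focused C>T
deamination, a flat clock-like profile, C>A-dominated damage, UV-like
CC>TT-adjacent C>T, APOBEC-like TpC) so that refitting examples are
well conditioned.  Run from the repository root:

    python scripts/make_reference_signatures.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from clonesoma.signatures import SPECTRUM_INDEX

OUT = Path(__file__).resolve().parents[1] / "src" / "clonesoma" / "data"


def shaped_profile(weights_fn, rng) -> np.ndarray:
    base = np.array([weights_fn(label) for label in SPECTRUM_INDEX], dtype=float)
    noise = rng.dirichlet(np.full(96, 0.5))
    prof = 0.9 * base / base.sum() + 0.1 * noise
    return prof / prof.sum()


def main() -> None:
    rng = np.random.default_rng(961)
    cols = {}

    cols["RS1"] = shaped_profile(
        lambda l: 12.0 if l[2:5] == "C>T" and l[6] == "G" else (1.0 if l[2:5] == "C>T" else 0.05),
        rng)
    cols["RS2"] = shaped_profile(
        lambda l: 8.0 if l[2:5] in ("C>T", "C>G") and l[0] == "T" else 0.05, rng)
    cols["RS3"] = shaped_profile(lambda l: 1.0, rng)  # flat
    cols["RS4"] = shaped_profile(
        lambda l: 6.0 if l[2:5] == "C>A" else 0.2, rng)
    cols["RS5"] = shaped_profile(lambda l: 1.0, rng)  # flat, clock-like
    cols["RS6"] = shaped_profile(
        lambda l: 5.0 if l[2:5] == "C>T" and l[0] in "AG" else 0.2, rng)
    cols["RS7"] = shaped_profile(
        lambda l: 10.0 if l[2:5] == "C>T" and l[0] in "CT" else 0.05, rng)
    cols["RS8"] = shaped_profile(
        lambda l: 4.0 if l[2:5] == "C>A" else (1.0 if l[2:5] == "C>T" else 0.3), rng)
    for i in range(9, 31):
        alpha = np.full(96, 0.3)
        hot = rng.choice(96, size=8, replace=False)
        alpha[hot] = 6.0
        prof = rng.dirichlet(alpha)
        cols[f"RS{i}"] = prof / prof.sum()

    df = pd.DataFrame(cols, index=list(SPECTRUM_INDEX))
    OUT.mkdir(parents=True, exist_ok=True)
    df.round(6).to_csv(OUT / "reference_signatures_synthetic.tsv", sep="\t",
                       index_label="context")
    print(f"wrote {OUT / 'reference_signatures_synthetic.tsv'} ({df.shape})")


if __name__ == "__main__":
    main()
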