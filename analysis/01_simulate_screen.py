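"""Generate the synthetic BAC screen used by the downstream stages.

Emulates the genotyping screen at study conditions: 1240 equally abundant
genotype classes, 342 clones sampled with replacement, 1-bp sizing jitter on
a fifth of marker calls, clone intervals on the 120-kb reference, and a
noiseless + noisy qPCR Ct table.  Writes results/synthetic/.
"""

from pathlib import Path

from bacrichness.copynumber import StandardCurve
from bacrichness.synthetic import simulate_qpcr, simulate_screen

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20090417  # master seed for the whole analysis

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth, screen = simulate_screen(
        theta=1240, n_clones=342, jitter_prob=0.2, seed=SEED
    )
    screen.to_tsv(OUT / "screen.tsv")
    print(f"screen: {screen.n_clones} clones from theta={truth.theta} classes; "
          f"{screen.n_true_distinct()} distinct truths sampled")
    print(f"minimum pairwise class separation: {truth.min_pairwise_separation()} bp")

    curve = StandardCurve(intercept=40.0, slope=-10 / 3)
    cts = simulate_qpcr(true_ratio=100.0, reference_copies=1_000.0, curve=curve,
                        sigma_ct=0.1, reps=3, seed=SEED + 1)
    cts.to_csv(OUT / "qpcr_cts.csv", index=False)
    import pandas as pd
    standards = pd.DataFrame(
        [(g, 10.0**j, curve.predict_ct(10.0**j))
         for g in ("target", "reference") for j in range(2, 8)],
        columns=["gene", "copies", "ct"],
    )
    standards.to_csv(OUT / "qpcr_standards.csv", index=False)
    print(f"wrote {OUT / 'screen.tsv'}, qpcr_cts.csv, qpcr_standards.csv")

if __name__ == "__main__":
    main()
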