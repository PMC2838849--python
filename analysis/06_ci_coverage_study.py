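"""Coverage study of the profile-likelihood CI at study conditions.

Simulates 200 screens of 342 clones from 1240 equally abundant classes,
re-estimates theta and the 95% CI for each, and reports how often the CI
contains the truth.  Nominal coverage is 95%; at 200 replicates the
binomial tolerance admits anything >= 89%.
"""

import json
from pathlib import Path

import numpy as np

from bacrichness.richness import ObservedRichness, mle_theta, profile_ci

ROOT = Path(__file__).resolve().parents[1] / "results"
THETA, N, REPS, SEED = 1240, 342, 200, 20090417

def main() -> None:
    rng = np.random.default_rng(SEED)
    hits, estimates = 0, []
    for _ in range(REPS):
        k = len(np.unique(rng.integers(0, THETA, size=N)))
        obs = ObservedRichness(n=N, k=k)
        theta_hat, unbounded = mle_theta(obs)
        if unbounded:
            continue
        lo, hi = profile_ci(obs, alpha=0.05)
        hits += lo <= THETA <= hi
        estimates.append(theta_hat)
    coverage = hits / REPS
    print(f"95% CI covered theta={THETA} in {hits}/{REPS} screens "
          f"({100 * coverage:.1f}%)")
    print(f"median theta_hat {int(np.median(estimates))}, "
          f"IQR ({int(np.percentile(estimates, 25))}, "
          f"{int(np.percentile(estimates, 75))})")
    out = ROOT / "richness"
    out.mkdir(parents=True, exist_ok=True)
    (out / "ci_coverage.json").write_text(json.dumps({
        "theta": THETA, "n": N, "replicates": REPS,
        "coverage": coverage, "median_theta_hat": float(np.median(estimates)),
    }, indent=2) + "\n")

if __name__ == "__main__":
    main()
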