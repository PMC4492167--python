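#!/usr/bin/env python
"""End-to-end parameter recovery on the emulated study design.

20 replicates of: simulate 145 RILs on paper-like chromosomes (reduced to
3 chromosomes for the default run), 3 planted QTLs of 0.25-0.40 progeny sd
each hitting 3 of 7 correlated traits, 4 blocks; run phenotype prep and the
MT-MIM forward search; compare recovered effects and 1.5-LOD intervals to
the planted truth. Writes recovery_effects.tsv and recovery_detections.tsv
under results/.
"""

from pathlib import Path

from rilqtl import studies

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    BASE.mkdir(parents=True, exist_ok=True)
    res = studies.recovery_study(n_reps=20, n_chrom=3, seed=1, K=200)
    res.effects.to_csv(BASE / "recovery_effects.tsv", sep="\t", index=False)
    res.detections.to_csv(BASE / "recovery_detections.tsv", sep="\t",
                          index=False)
    print(f"{len(res.detections)} detections over {res.n_reps} replicates "
          f"(3 planted QTLs each)")
    print(f"mean |per-effect bias| (analysis sd units): "
          f"{res.mean_abs_bias:.3f}")
    print(f"1.5-LOD interval coverage of the true position: "
          f"{100 * res.interval_coverage:.1f}%")


if __name__ == "__main__":
    main()
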