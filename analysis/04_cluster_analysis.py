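#!/usr/bin/env python
"""Cluster-level analysis: membership, over-representation, severity, profiles.

From the archived K=4 fit: per-dyad membership profiles over the posterior
draws, the group x cluster over-representation table with its chi-square
tests, the membership-severity correlations for the scored clinical
groups, and per-cluster coefficient/trajectory profiles.
"""

from pathlib import Path

import pandas as pd

from trustmix import io
from trustmix.cluster_analysis import (
    cluster_profiles,
    membership_profiles,
    overrep_table,
    severity_correlation,
)
from trustmix.design import monomial_labels

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    severity = io.read_severity_csv(ROOT / "population" / "severity.csv")
    records = io.read_dyads_csv(ROOT / "population" / "dyads.csv",
                                severity=severity)
    chain = io.load_chain(ROOT / "fit" / "chain_k4.json")
    out = ROOT / "clusters"
    out.mkdir(parents=True, exist_ok=True)

    profiles = membership_profiles(chain, [r.dyad_id for r in records])
    K = chain.spec.K
    pd.DataFrame([
        {"dyad_id": p.dyad_id,
         **{f"freq_{k + 1}": p.frequencies[k] for k in range(K)},
         "modal": p.modal + 1}
        for p in profiles
    ]).to_csv(out / "membership.csv", index=False)

    table = overrep_table(profiles, {r.dyad_id: r.group for r in records})
    table.cells.to_csv(out / "overrep_cells.csv", index=False)
    table.group_tests.to_csv(out / "overrep_tests.csv", index=False)
    thr = table.group_tests["per_term_threshold"].dropna().iloc[0]
    print(f"per-term significance threshold |z| = {thr:.2f}")
    print("\nstrongest over-representation per group:")
    for g, sub in table.cells.groupby("group"):
        best = sub.loc[sub["z"].idxmax()]
        flag = " *" if best["z"] > thr else ""
        print(f"  {g:8s} cluster {int(best['cluster'])}  "
              f"z = {best['z']:+.2f}{flag}")

    print("\nmembership-severity correlations (modal members):")
    rows = []
    for scale, group_names in (("ADI-R-repetitive", ("ASD",)),
                               ("interpersonal-trust", ("BPD-M", "BPD-N"))):
        ids = {r.dyad_id for r in records
               if r.group in group_names and r.severity}
        scores = {r.dyad_id: r.severity[scale] for r in records
                  if r.dyad_id in ids}
        sub_cells = table.cells[table.cells["group"].isin(group_names)]
        cluster = int(sub_cells.loc[sub_cells["z"].idxmax(), "cluster"]) - 1
        group_profiles = [p for p in profiles if p.dyad_id in ids]
        for restrict in (True, False):
            scope = "modal members" if restrict else "all scored dyads"
            try:
                r_val, p_val, n = severity_correlation(
                    group_profiles, scores, cluster,
                    restrict_to_modal=restrict,
                )
                print(f"  {scale:20s} cluster {cluster + 1} ({scope}): "
                      f"r = {r_val:+.2f}, p = {p_val:.3g}, n = {n}")
                rows.append({"scale": scale, "cluster": cluster + 1,
                             "scope": scope, "r": r_val, "p": p_val,
                             "n": n})
            except ValueError as err:
                print(f"  {scale:20s} ({scope}): not computable ({err})")
    pd.DataFrame(rows).to_csv(out / "severity_correlations.csv", index=False)

    prof = cluster_profiles(chain, records,
                            monomial_labels(chain.spec.P, chain.spec.D))
    pd.DataFrame([
        {"cluster": p.cluster + 1, "n_members": p.n_members,
         **{f"beta[{lbl}]": b
            for lbl, b in zip(p.beta_labels, p.mean_beta)},
         **{f"mean_i{t + 1}": v
            for t, v in enumerate(p.mean_investments)},
         **{f"mean_r{t + 1}": v
            for t, v in enumerate(p.mean_repayments)}}
        for p in prof
    ]).to_csv(out / "cluster_profiles.csv", index=False)
    print("\ncluster sizes and mean round-10 investment:")
    for p in prof:
        print(f"  cluster {p.cluster + 1}: n = {p.n_members:3d}, "
              f"mean i10 = {p.mean_investments[-1]:.2f}")
    io.write_manifest(out, {"script": "04_cluster_analysis"})


if __name__ == "__main__":
    main()
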