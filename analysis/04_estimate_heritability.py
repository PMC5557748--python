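"""Estimate narrow-sense heritability of the diversity phenotype.

For each study the Bayesian animal model yields the posterior of
h2 = sigma2_A / (sigma2_A + sigma2_E) over the pedigree's relationship
matrix, summarized by mode (headline), mean +/- SD and the 95% central
credibility interval.  Parent-offspring regressions give the frequentist
counterpart: midparent slope (= h2) for the two-parent design, twice the
dam slope for the maternal design.  Maternal-environment effects are
screened by DIC (lower wins).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from symh2.animal_model import (
    MCMCSettings,
    ModelSpec,
    compare_maternal_models,
    gibbs_animal_model,
    write_chains_tsv,
)
from symh2.io import read_metadata
from symh2.pedigree import additive_relationship_matrix, read_pedigree
from symh2.regression import midparent_regression, single_parent_regression

BASE = Path(__file__).resolve().parent.parent / "results"
SETTINGS = MCMCSettings(n_iterations=60_000, burn_in=0.10, thinning=25, seed=7)


def analyse(name: str) -> dict:
    data = BASE / "data" / name
    ped = read_pedigree(data / "pedigree.csv")
    meta = read_metadata(data / "metadata.csv")
    traits = pd.read_csv(BASE / name / "traits.tsv", sep="\t")
    trait = dict(zip(traits["sample_id"], traits["D"]))
    parent_of = {r.individual_id: (r.sire_id, r.dam_id) for r in ped.records}
    A = additive_relationship_matrix(ped)

    offspring = [
        (meta.individual(s), trait[s])
        for s, (_, stage, _, _) in meta.records.items()
        if stage != "adult"
    ]
    adult_trait = {
        meta.individual(s): trait[s]
        for s, (_, stage, _, _) in meta.records.items()
        if stage == "adult"
    }

    spec = ModelSpec(
        y=np.array([t for _, t in offspring]),
        individual_ids=[i for i, _ in offspring],
        dam_ids=[parent_of[i][1] or i for i, _ in offspring],
    )
    fit = gibbs_animal_model(spec, A, SETTINGS, include_maternal=False)
    write_chains_tsv(fit, BASE / name / "chains.tsv")
    comparison = compare_maternal_models(spec, A, SETTINGS)

    if name == "diallel":
        parents, records = {}, []
        for ind, t in offspring:
            sire, dam = parent_of[ind]
            fam = f"{sire}x{dam}"
            parents[fam] = (adult_trait[dam], adult_trait[sire])
            records.append((fam, t))
        reg = midparent_regression(records, parents)
    else:
        records = [(parent_of[ind][1], t) for ind, t in offspring]
        reg = single_parent_regression(records, adult_trait)

    result = {
        "bayes": fit.to_dict(),
        "regression": reg.to_dict(),
        "maternal_comparison": {
            "dic_no_maternal": comparison.no_maternal.dic,
            "dic_maternal": comparison.maternal.dic,
            "selected": comparison.selected,
        },
    }
    s = fit.summary
    print(
        f"{name}: h2 mode {s.mode:.3f}, mean {s.mean:.3f} +/- {s.sd:.3f}, "
        f"95% CI [{s.ci95[0]:.3f}, {s.ci95[1]:.3f}]; "
        f"{reg.mode} regression h2 = {reg.h2:.3f} (slope {reg.slope:.3f}); "
        f"DIC favours {comparison.selected}"
    )
    return result


def main() -> None:
    out = {name: analyse(name) for name in ("diallel", "maternal")}
    path = BASE / "heritability.json"
    path.write_text(json.dumps(out, indent=2))
    print(f"results -> {path}")


if __name__ == "__main__":
    main()
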