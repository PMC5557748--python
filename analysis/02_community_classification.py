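"""Normalize both study count tables and classify OTUs.

Counts are variance-normalized with median-of-ratios size factors, then
each OTU is labelled by abundance (principal vs background at 0.01% of
total normalized reads) and ubiquity (core >75%, common 25-75%, rare <25%
of samples).  Expect a few principal/core OTUs over a long rare background
tail, the hallmark of these symbiont communities.
"""

from pathlib import Path

from symh2 import abundance as ab
from symh2.io import read_count_table

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for name in ("diallel", "maternal"):
        table = read_count_table(BASE / "data" / name / "counts.tsv")
        norm = ab.normalize(table, ab.size_factors(table))
        cls = ab.classify(table, norm)
        out = BASE / name
        out.mkdir(parents=True, exist_ok=True)
        ab.write_classification(cls, out / "classification.tsv")
        n_bg = sum(1 for v in cls.abundance_class.values() if v == "background")
        n_rare = sum(1 for v in cls.ubiquity_class.values() if v == "rare")
        print(
            f"{name}: {table.n_otus} OTUs -> "
            f"{table.n_otus - n_bg} principal / {n_bg} background; "
            f"{n_rare} rare, "
            f"{sum(1 for v in cls.ubiquity_class.values() if v == 'core')} core"
        )


if __name__ == "__main__":
    main()
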