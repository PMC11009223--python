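# nasogut

Analysis toolkit for a question in pig respiratory microbiology: how much of
the piglet **nasal** microbiota is made up of **gut-associated bacteria**, where
do those bacteria come from, and are they metabolically active in the nose?

The package works on standard 16S rRNA amplicon artifacts — an ASV
(amplicon sequence variant) count table, a Greengenes-style taxonomy
assignment table and sample metadata, all as QIIME2-export TSV — and
implements the four bespoke analyses such a study needs, plus a simulator
that generates paired-site datasets with known ground truth so the whole
pipeline can be validated without touching real sequencing data.

## What it computes

1. **Gut-associated fraction** (`composition`): per sample, the summed
   relative abundance of the orders *Bacteroidales* and *Clostridiales*
   (the dominant gut orders), with mean ± SD per stratum, plus the
   four-part order summary used in stacked-bar figures (gut orders /
   "Other" above a mean-abundance display threshold / "Low abundant").
   An alternative, data-driven gut definition (`reference_gut`) calls a
   taxon gut-associated when it is prevalent in a reference gut cohort.
2. **Body-site overlap** (`overlap`): within each farm, the top-N most
   abundant ASVs of a taxon group in nasal and in rectal samples are
   intersected. With ASV identity as exact sequence equality, the shared
   percentage `100·|top_nasal ∩ top_rectal| / |top_nasal ∪ top_rectal|`
   (or `/N`) measures whether the same strains occupy both sites; ASVs
   shared in every farm form the cross-farm shared set.
3. **Activity ratios** (`activity`): with paired DNA (16S gene) and RNA
   (16S transcript) libraries per animal, a taxon's RNA/DNA
   relative-abundance ratio proxies its protein-synthesis potential.
   Ratio-of-means per taxon, per-animal group sums, and a rank-based
   (Mann–Whitney, Benjamini–Hochberg adjusted) comparison of each
   family's per-animal ratio distribution against pooled nasal-colonizer
   families.
4. **Decontamination** (`qc_filters`): ASVs detected in negative-control
   (blank) libraries are removed per nucleic-acid type, and
   Archaea/chloroplast/mitochondria ASVs are discarded.
5. **Simulation** (`synthetic_data`): per-farm ASV pools partially shared
   between nasal and rectal sites; log-normal base abundances; per-animal
   Dirichlet variation (concentration α₀); multinomial read counts at
   log-normal depths; per-family RNA activity factors; spiked control
   contaminants — everything recorded in a truth ledger for recovery tests.

## Worked example

```python
from nasogut import (SimConfig, generate_dataset, remove_control_asvs,
                     to_relative, gut_fraction, TaxonGroupFilter,
                     top_n_asvs, classify_overlap)

cfg = SimConfig(seed=1, target_order_fractions={"Bacteroidales": 0.10,
                                                "Clostridiales": 0.20})
table_dna, table_rna, tax, meta, truth = generate_dataset(cfg)

table_dna, report = remove_control_asvs(table_dna, meta)
print(report.counts_removed)            # {'control_dna': 21}

rel = to_relative(table_dna)
frac = gut_fraction(rel, tax)
nasal = list(meta.subset(body_site="nasal", molecule="DNA",
                         is_control=False)["sample_id"])
print(frac.loc[nasal].mean().round(4).to_dict())
# {'bacteroidales': 0.1069, 'clostridiales': 0.1943}

gut = TaxonGroupFilter("order", frozenset(["Bacteroidales"]))
ids = list(meta.subset(farm="farm1", body_site="nasal", molecule="DNA",
                       is_control=False)["sample_id"])
top_nasal = top_n_asvs(rel.select_samples(ids), tax, gut, 20)
ids = list(meta.subset(farm="farm1", body_site="rectal", molecule="DNA",
                       is_control=False)["sample_id"])
top_rectal = top_n_asvs(rel.select_samples(ids), tax, gut, 20)
print(round(classify_overlap(top_nasal, top_rectal).shared_pct, 1))
# 48.1
```

The 21 removed ASVs are the planted DNA-control contaminants; the nasal
gut fractions recover the planted 10 % / 20 % order composition within
sampling error; and 48.1 % of the top-20 *Bacteroidales* ASVs (union
denominator) are shared between farm 1's nasal and rectal samples.

The same stages are available from the shell:

```bash
nasogut simulate --seed 1 --out run/sim
nasogut filter  --table run/sim/table_dna.tsv --taxonomy run/sim/taxonomy.tsv \
                --metadata run/sim/metadata.tsv --out run/filt
nasogut gutfrac --table run/filt/filtered_table.tsv --taxonomy run/sim/taxonomy.tsv \
                --metadata run/sim/metadata.tsv --out run/gut
```

Each run directory gets a `manifest.json` with input digests, the seed
and the package version.

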