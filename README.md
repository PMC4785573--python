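# famrisk

Family-genomics analysis toolkit for multiply-affected disease families:

* **Synthetic cohorts** — gene-drop simulation of pedigree genomes with
  Poisson recombination (default 35.3 crossovers per meiosis allocated to
  chromosomes by physical length), founder haplotype models with injected
  family-private rare variants, liability-based phenotypes, and
  Hardy–Weinberg control panels.
* **Identical-by-descent segments** — meiosis counting on arbitrary
  pedigrees, exact enumeration of inheritance vectors for the probability
  that all targets share a founder haplotype at a point, a genome-wide
  sharing model (`1 − (1 − p)^(C + m·rho)`), a gene-drop Monte-Carlo oracle,
  inheritance-state inference for nuclear families, and a rare-allele
  sharing scan.
* **Candidate-variant filtering** — quality / population-frequency /
  consequence / gene-panel-distance cascade with shared-het,
  homozygous-recessive and compound-het (trans-phased via parents) zygosity
  models.
* **Polygenic risk scores** — subtype-specific scores
  (`sum of allele count × ln OR`), one-sided Wilcoxon rank-sum, ROC/AUC,
  Nagelkerke pseudo R², parent→offspring transmission ratios, and
  per-family summaries.

## CLI

The `famrisk` command runs the pipeline end to end or stage by stage from a
single JSON config (see `examples/run.json`; `seed` is required):

```sh
famrisk run --config examples/run.json            # simulate -> ibd -> filter -> prs -> report
famrisk simulate --config examples/run.json       # single stage
famrisk prs --config examples/run.json --seed 7   # seed override
```

Each stage reads/writes plain text formats under `out_dir` (multi-sample
VCF, 6-column PED with CD/UC affection codes, locus-weight TSV, gene-panel
TSV, BED3+ segments, JSON reports), so stages can be re-run in isolation.
Outputs are byte-identical for a fixed seed; `manifest.json` records the
config hash, versions and per-stage record counts.

## Library example

```python
from famrisk.pedigrees import two_branch_family
from famrisk.synthetic import GRCH37_AUTOSOMES, build_genetic_map
from famrisk.ibd import genome_sharing_probability

ped = two_branch_family()                # 5 affecteds, 15 connecting meioses
gmap = build_genetic_map(GRCH37_AUTOSOMES, 35.3)
genome_sharing_probability(ped, ped.affected(), gmap)   # ~0.065
```

## Layout

```
src/famrisk/
  io_formats.py   PED/VCF/BED/TSV readers & writers, domain types
  synthetic.py    genetic maps, gene drop, locus tables, phenotypes, controls
  pedigrees.py    programmatic pedigree builders (nuclear, chains, deep families)
  ibd.py          meiosis graphs, sharing probabilities, state inference, segments
  filtering.py    candidate-variant cascade and zygosity models
  prs.py          risk scores and case/control / transmission statistics
  pipeline.py     stage orchestration, config validation, manifest
  cli.py          click command group
tests/            pytest suite (tests/test_acceptance.py covers the
                  acceptance criteria)
scripts/acceptance.py
```
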