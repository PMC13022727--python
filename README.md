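# retrostrat

Synthon-abstracted ("higher-level") computer-aided retrosynthesis.

Classical retrosynthesis tools reason over fully specified molecules, so
a single synthetic strategy — say, an amide coupling — is scattered over
dozens of concrete variants that differ only in the leaving group (acid,
ester, acyl chloride) or in protecting groups.  `retrostrat` implements a
pipeline that reasons at the level of *strategy* instead:

1. **Route mining** — per-document collections of atom-mapped reactions
   are assembled into a reaction network; multistep routes are extracted
   for each terminal product, and every atom of every intermediate is
   traced through the map numbers to decide whether its lineage reaches
   the target (*core*) or not (*leaving*).
2. **Abstraction** — leaving substructures are deleted and replaced by
   polarity-classed markers on their core attachment atoms.  A marker is
   an attachment-point pseudo-atom (`[1*]`–`[4*]`) whose class follows
   the Pauling electronegativity of the attached leaving atom relative to
   carbon: HET for heteroatom cores, C(+) for electrophilic carbons
   (halide/triflate-type partners), C(−) for nucleophilic carbons
   (boron/silicon-type partners, C–H nucleophile equivalents), and C(0)
   in a neutral band of ±0.1 Pauling units.  Reactions that only
   transform leaving substructures (leaving-group FGIs, protections)
   become identities after abstraction and are removed from the route.
3. **Single-step model** — retro templates (product pattern →
   precursor patterns, marker-aware) are extracted from each unique
   reactant–product pair and consolidated to the most general template
   that recovers the recorded reactants.  A feedforward network maps a
   product's marker-aware Morgan count fingerprint to template scores;
   accuracy is reported as *pessimistic top-k*: the recorded precursor
   set is ranked last within the block of proposals generated by its own
   template.
4. **Multistep planning** — a Monte Carlo tree search
   (select → expand → update, PUCT selection) expands abstracted
   intermediates until they match a building-block catalog.  The
   *original* mode requires an exact catalog hit; the *higher-level*
   mode uses marker-aware substructure search, so an abstracted aryl
   electrophile `[2*]c1ccccc1` terminates at bromobenzene, chlorobenzene
   or phenyl triflate alike.

Because public reaction corpora are large and unwieldy for testing, the
package ships a synthetic corpus generator
(`retrostrat.corpus`) that emulates patent-like multistep routes —
scaffold couplings, amide/ester/sulfonamide formations, protections and
leaving-group FGIs — with exact planted ground truth (leaving atoms,
tactical steps, route statistics) constructed alongside the atom maps.

## Worked example

```bash
retrostrat simulate --n-documents 40 --seed 21 --out-dir out/sim
retrostrat curate   --corpus out/sim/corpus.tsv --seed 21 --out-dir out/cur
retrostrat train    --corpus out/sim/corpus.tsv --seed 3  --out-dir out/train
echo 'CC#Cc1csc(CSc2c(C(=O)N(C)C)nc(C(=O)OC)c(F)c2F)c1' > targets.txt
retrostrat plan     --targets-file targets.txt \
                    --model out/train/model.pkl --buyables out/sim/buyables.txt \
                    --mode higher --max-iterations 300 --expansion-width 50 \
                    --out-dir out/plan
```

`simulate` reports `wrote 141 records (40 documents)` and `curate`
prints

```
129 unique pairs from 40 routes
```

meaning 40 multistep routes were mined and their steps deduplicated to
129 higher-level strategies.  `train` prints the held-out top-k table in
both conventions:

```
pessimistic top-k accuracy (%):
  k   top-k accuracy (%)
  1     38.5
  3     84.6
  5    100.0
```

the percentage of held-out products whose recorded precursor set
appears among the k highest-ranked proposals (40 documents leave only
~100 training pairs, so per-template ranking is rough at k=1 while the
correct strategy is always recovered by k=5; the 700-document corpus
used by the acceptance script reaches ~93% pessimistic top-1).  Finally
`plan` reports

```
solved 1/1 targets (100.0%)
```

with per-target routes, depths, reaction counts, and the buyable
molecules matching each starting material written to `routes.json` — the
matches are the concrete building blocks a chemist would pick from when
instantiating the abstract route.

The same machinery is importable as a library; see
`retrostrat.pipeline.curate` and `retrostrat.pipeline.train_pipeline`
for the end-to-end entry points used by the CLI.

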