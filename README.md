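# vscreen

A ligand-based virtual screening funnel for antagonist discovery, built as a
tested library plus CLI. It covers the full multi-step workflow:

1. **Activity curation** (`vscreen.chem_data`) — parse activity tables,
   label compounds by strict pKi thresholds (> 8 active, < 6 inactive,
   mid-range excluded), stratified 7:2:1 train/test/validation splitting with
   largest-remainder apportionment, average-linkage Tanimoto clustering with
   medoid representatives, and property-matched decoy selection.
2. **Fingerprints & graphs** (`vscreen.fingerprints`) — ECFP4 bit
   fingerprints, Tanimoto similarity / max-Tc novelty, and molecular graph
   encodings for the neural-fingerprint network.
3. **Classifiers** (`vscreen.deep_models`) — a dense feedforward network on
   ECFP4 bits and a graph-convolutional neural-fingerprint network, both
   pure NumPy (Adam, binary cross-entropy, L2, dropout, early stopping,
   fully seeded); six evaluation indicators (SE, SP, Q+, Q−, MCC, AUC) and a
   batch-size sweep that selects the best model by AUC.
4. **Pharmacophores** (`vscreen.pharmacophore`) — SMARTS-based 3D feature
   perception (acceptor/donor/hydrophobe/ring/charge), common-feature
   hypothesis generation via distance hashing plus Kabsch superposition, and
   k-of-n partial-match screening.
5. **Enrichment metrics** (`vscreen.ranking_metrics`) — EF at a top
   fraction, BEDROC(α) in the exact closed form, ROC area, and AUAC.
6. **Funnel** (`vscreen.funnel`) — classifier consensus → pharmacophore
   filter → cascade top-percentage filtering over external docking score
   tables → annotated shortlist with novelty scores. Docking is consumed
   from TSV files, never computed.
7. **Synthetic fixtures** (`vscreen.synthetic`) — seeded generators for
   labeled fingerprint datasets, motif-planted molecule libraries, rigid 3D
   molecules realizing a known pharmacophore geometry, and ranked screens
   with prescribed active placement. All tests run from these; no downloads.

## CLI

```bash
vscreen curate --activities activities.csv --out-dir curated/
vscreen train dnn --data curated/curated.csv --out dnn.json
vscreen sweep dnn --data curated/curated.csv --sizes 50,100,150 --out sweep.tsv
vscreen evaluate --model dnn.json --data curated/curated.csv
vscreen pharm-build --actives actives.sdf --min-actives 5 --out hyps.json
vscreen pharm-screen --library library.sdf --hypothesis hyps.json --k 4 --out ranked.tsv
vscreen decoys --actives curated/curated.csv --pool pool.smi --out decoys.csv
vscreen enrich --screen ranked.tsv
vscreen novelty --query hits.smi --references known.smi
vscreen funnel --config funnel.json --library library.sdf --out report.json
```

Run `vscreen COMMAND --help` for options. Global flags: `--seed`,
`--log-level`.

## Notes

- Everything is deterministic for a fixed seed, CPU-only, and desk-scale.
- Fingerprint bit indices are implementation-specific: rely on similarity
  values and invariances, never on particular bits.
- The pharmacophore module is an open re-specification of a common-feature
  workflow; no numerical agreement with proprietary tools is claimed.
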