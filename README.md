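# circabs

Alternative back-splicing (ABS) analysis of circular RNAs, from per-sample
back-splice junction tables to event catalogs, saturation-corrected ABS
prevalence, tissue specificity, and flanking-intron sequence features.

Circular RNAs (circRNAs) form when a downstream 5′ splice donor is joined
back to an upstream 3′ splice acceptor.  A single locus often produces
several circRNAs that share one back-splice site: two or more donors
joined to one acceptor make an **A5BS** (alternative 5′ back-splicing)
event, two or more acceptors joined to one donor an **A3BS** event, and a
circRNA that shares neither site with another circRNA is **constitutive**.
This package is for transcriptomics researchers who have circRNA junction
calls (e.g. from CIRCexplorer2- or CIRI2-style callers, as BED-like
tables) across multiple tissues or samples and want to quantify how
prevalent ABS is, which circRNA dominates each event where, and which
genomic features track that choice.

## What it computes

* **Event catalog** — circRNAs keyed by `(chrom, strand, acceptor, donor)`
  are normalized to RPM (back-splice junction reads per million mapped
  reads), averaged across replicates, and flagged high-confidence at
  ≥ 0.1 RPM in at least one tissue.  Events need ≥ 2 high-confidence
  members; every high-confidence circRNA gets exactly one label from
  {A5BS, A3BS, A5BS&A3BS, constitutive}.  Event *complexity* is the
  number of member circRNAs (low = 2, high ≥ 3).
* **Saturation-corrected ABS fraction** — the observed ABS fraction rises
  with junction-read coverage because rare event partners drop below the
  detection threshold.  circRNAs are binned by pooled abundance x and the
  per-bin ABS fraction is fitted with the sigmoid

  F(x) = α / (1 + e^−(x−m)·n),

  whose upper asymptote α estimates the ABS fraction at saturating
  sequencing depth.  Estimates are checked for robustness across bin
  sizes (50–500 circRNAs per bin).
* **PCU and tissue specificity** — the *predominant* circRNA of an event
  is the member that is most abundant in the majority of tissues within a
  cohort scope; its **PCU** (Percent Circularized-site Usage) in a tissue
  is its share of the event's junction reads, in percent.  Events whose
  largest pairwise PCU difference (ΔPCU) across eligible tissues reaches
  a cutoff are tissue specific.  Cross-sample Spearman correlations and
  average-linkage clustering of tissues summarize the structure.
* **Flanking-intron features** — introns flanking each circRNA (in gene
  orientation) are pulled from a genePred/refFlat annotation; lengths and
  overlapping Alu elements are compared across complexity classes and
  between predominant and other members (Wilcoxon rank-sum / signed-rank),
  plus a CSI-style score of the strongest inverted-Alu pairing between
  the two flanking introns.
* **Synthetic data** — `circabs.simulate` generates gene models, Alu
  annotations, and multi-tissue junction tables with fully known planted
  truth (labels, complexity, predominant members, per-tissue PCU, feature
  effects), so the whole pipeline is tested closed-loop.

## Worked example

```python
from circabs import io, events, saturation, pcu
from circabs.simulate import SimConfig, simulate

sim = simulate(SimConfig(seed=1))   # 5,000 circRNA loci, 8 tissues x 2 replicates
per_sample = io.normalize_rpm(sim.junctions, sim.sample_sheet)
tissue = io.average_replicates(per_sample, sim.sample_sheet)
hc = io.filter_high_confidence(tissue)          # >= 0.1 RPM in >= 1 tissue
evs = events.filter_high_confidence_events(events.group_events(tissue.index, hc))
labels = events.classify_circrnas(evs, tissue.index[hc])

print(f"high-confidence circRNAs: {int(hc.sum())} of {len(tissue)} detected")
print(labels.value_counts().to_string())

pooled = saturation.pool_abundance(tissue, hc)
fit = saturation.fit_sigmoid(saturation.bin_fractions(pooled, labels, bin_size=50))
print(f"ABS fraction at saturating coverage: alpha = {fit.alpha:.3f}")

pred = pcu.select_predominant(evs, tissue)
mat = pcu.compute_pcu(evs, tissue, pred)
calls = pcu.call_tissue_specific(mat, cutoff=40)
print(f"tissue-specific events at dPCU >= 40: {100 * calls.specific.mean():.1f}%")
```

prints

```
high-confidence circRNAs: 3325 of 4783 detected
label
A5BS            1257
A3BS            1040
constitutive     912
A5BS&A3BS        116
ABS fraction at saturating coverage: alpha = 0.864
tissue-specific events at dPCU >= 40: 36.7%
```

The generator planted ABS for 84% of the 5,000 loci; only 72.6% of the
*detected* high-confidence circRNAs are observed in an event (their
partners are censored at low coverage), and the sigmoid extrapolates the
asymptote back to 0.864.  A5BS outnumbers A3BS, and at a strict 40-point
ΔPCU cutoff about a third of events remain tissue specific.

The same steps are available from the shell via the `circabs` command
(`simulate`, `normalize`, `call-events`, `saturation`, `pcu`, `features`);
each subcommand reads and writes plain TSV/JSON files.

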