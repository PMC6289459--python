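# gofish

Design and analysis toolkit for species-specific **nested-PCR eDNA assays**
built inside a broad-range mitochondrial 12S metabarcoding amplicon.

Single-species environmental-DNA assays of this kind work in two rounds: a
"universal" first-round PCR with broad-range vertebrate 12S primers (the
MiFish segment, ~220 bp including primers), followed by nested PCR with
species-specific, M13-tailed primers that prime inside the first-round
product. A gel-positive nested product is Sanger-sequenced with universal M13
primers, and a detection is scored only when the read matches a reference
100% over its full length. The approach needs no tissue samples or qPCR
equipment, but it stands or falls on primer design: the nested primers must
discriminate the target from every co-occurring species at the 3' end, and
the short amplified segment must itself contain diagnostic differences.

This package automates that design workflow and the downstream
presence/absence analysis for anyone building such assays from a reference
alignment: eDNA practitioners, molecular ecologists, and teaching labs.

## What it computes

**Primer thermodynamics** (`gofish.thermo`) — nearest-neighbor melting
temperatures with the unified parameter set (SantaLucia 1998) and the
Owczarzy 2004 sodium correction,

```
Tm = ΔH° / (ΔS° + R ln CT)   (1 M Na+),
1/Tm(Na+) = 1/Tm(1M) + (4.29 fGC − 3.95)·10⁻⁵ ln[Na+] + 9.40·10⁻⁶ ln²[Na+]
```

under reconstructed vendor-calculator defaults (0.25 µM oligo, 50 mM Na⁺,
oligo and complement equimolar). Mismatches are classified with permissive
wobble semantics: G·T/T·G primer–template pairs are tolerated and never count
toward the penalized-mismatch tally that confers specificity.

**Virtual PCR** (`gofish.insilico`) — degenerate-aware binding-site search on
both strands and single-round or nested amplicon prediction over a reference
panel, with amplicon lengths counted primer-to-primer.

**Alignment summaries** (`gofish.panelmatrix`) — consensus calling, p-distance
matrices, Saitou–Nei neighbor joining with a deterministic tie-break, and the
NJ-sorted difference-from-consensus matrix a primer designer reads by eye.

**Assay design** (`gofish.design`) — exhaustive candidate enumeration inside
the first-round amplicon, per-non-target 3'-mismatch audits (≥2 penalized
mismatches in the 3'-terminal window against every non-target), internal
diagnostic-position checks, ranking, and M13 tail attachment. Targets that
share their segment with another species raise `NoDesignPossible` naming the
indistinguishable taxa.

**Detection analysis** (`gofish.detect`) — strict 100% full-length species
assignment, presence/absence matrices with per-cell provenance, the 0.1%
per-OTU read filter, two-sided Fisher exact seasonal contrasts, and
two-method concordance with apparent sensitivity (method detections / union
of detections) and read-abundance stratification.

**Synthetic data** (`gofish.synth`) — seeded generators for 12S-like panels
(exact primer-site flanks, hypervariable interiors, optional twin species)
and seasonal detection time series, so the whole pipeline is testable without
any downloads.

## Worked example

```python
from gofish import (SynthPanelSpec, generate_panel, extract_region,
                    DesignCriteria, design_assay, melting_temperature)

print(round(melting_temperature("GTCGGTAAAACTCGTGCCAGC"), 1))  # 59.4

spec = SynthPanelSpec(seed=7)                  # 12 species + 1 twin pair
panel, aln, truth = generate_panel(spec)
interior = extract_region(aln, 21, aln.length - 27)
taxon_of = {r.id: r.taxon for r in panel}

best = design_assay(interior, panel.taxa[0],
                    DesignCriteria.preset("observed"),
                    taxon_of=taxon_of, max_designs=1)[0]
print(best.fwd_tailed)   # TGTAAAACGACGGCCAGTCGATAACCAGGCCTGTAATC
print(best.rev.tm)       # 53.08787856135996
print(best.amplicon_size_incl_tails)  # 149
```

The first number is the melting temperature (°C) of the universal forward
primer under the default conditions. The designed forward primer is emitted
5'→3' as synthesized — the 18 nt M13 forward tail followed by the
species-specific core — and the amplicon size is reported on the published
convention that includes both primers and their tails.

The same operations are exposed on the command line:

```
gofish tm GTCGGTAAAACTCGTGCCAGC
gofish simulate panel --seed 7 --out demo/
gofish design --alignment demo/panel_aligned.fa --target SYN000 --preset observed
gofish matrix --alignment demo/panel_aligned.fa
```

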