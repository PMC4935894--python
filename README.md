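# basestack

Tools for asking how 5-methylcytosine — in particular in the non-CpG (mCH)
contexts abundant in stem cells and neurons — changes the way transcription
factors engage their DNA elements, from three angles:

* **DNA conformation.** The stacking-overlap area *S*<sub>OA</sub> of every
  base-pair step of a duplex: the heterocyclic rings of the four bases of two
  adjacent pairs are projected onto the plane perpendicular to the local helix
  axis and the cross-step ring-polygon intersections are summed (Å²; van der
  Waals radii and exocyclic groups, including the 5-methyl, excluded).
  Because the methyl is not part of the ring outline, methylation can change
  *S*<sub>OA</sub> only through the conformation it induces — which is
  exactly what the statistic is designed to expose. Steps are classified into
  the 10 strand-symmetric dinucleotide classes (16 raw dinucleotides modulo
  reverse complementation), with methylation marks carried through.
* **Protein–DNA contacts.** Heavy-atom hydrogen bonds and water bridges,
  targeted distances (e.g. a histidine side-chain nitrogen to a backbone
  phosphate oxygen), all-DNA-heavy-atom RMSD after Kabsch superposition, and
  distance distributions over multi-model coordinate ensembles.
* **Binding kinetics.** Dissociation rates from single-molecule residence
  times via the right-censored exponential maximum-likelihood estimate
  k<sub>off</sub> = n<sub>events</sub> / (Σt + n<sub>censored</sub>·window),
  association rates via k<sub>on</sub> = k<sub>off</sub>/K<sub>D</sub>, and
  fold changes, all with first-order error propagation.

A synthetic-data module generates every input the pipeline needs: idealized
B-form duplexes of arbitrary (optionally methylated) sequence built from
standard base reference-frame templates, perturbed coordinate ensembles, and
censored exponential dwell-time samples — all seed-reproducible.

## Worked example

```sh
python analysis/02_stacking_profiles.py
```

builds the glucocorticoid response element GRE (AGAACATCATGTTCT), its
side-methylated variant smGRE (four mCH sites across the two half-sites on
both strands) and middle-methylated mmGRE (one spacer mCH), computes each
per-step *S*<sub>OA</sub> profile, and prints:

```
gre: 14 steps, total S_OA 24.49 A^2 -> results/soa_gre.tsv
smgre: 14 steps, total S_OA 27.16 A^2 -> results/soa_smgre.tsv
mmgre: 14 steps, total S_OA 24.49 A^2 -> results/soa_mmgre.tsv
smgre vs gre: 2 changed steps, max |delta| 1.347 A^2
mmgre vs gre: 0 changed steps, max |delta| 0.000 A^2
most methylation-sensitive class: AC (mean delta +1.338 A^2 over 2 steps)
```

Reading: the two A-mC steps of the built smGRE (one per strand, both in the
5′-AC-3′ context) gain ≈1.3 Å² of stacking overlap each under the documented
methylation-coupled slide, every other step is untouched, and ranking the
step classes by mean |Δ*S*<sub>OA</sub>| at methylation-bearing steps puts
the AC/AmC class first — the context where methylation changes DNA
conformation the most. The other drivers under `analysis/` build the duplex
panel, pool class-wise *S*<sub>OA</sub> box statistics over perturbed
ensembles, demonstrate the contact detectors, fit the kinetics, and (when
`data/pdb/` is populated) run the crystal-structure comparisons.

The same operations are scriptable from the shell, e.g.:

```sh
basestack synth bdna --seq AGAACATmCATGTTCT --out mmgre.pdb
basestack soa mmgre.pdb --strands A,B
basestack synth dwell --koff 0.1 --n 5000 --window 60 --seed 7 --out times.txt
basestack koff times.txt --window 60 --kd 1e-8 --kd-se 1e-9
```

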