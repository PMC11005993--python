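# Methods

## Coordinate conventions

Genomic coordinates are 0-based internally; TSS tables are BED-like
(single-base, half-open). All user-facing positions are TSS-relative
integers with the TSS base at 0 and upstream negative. Promoter windows are
`[-U, +D]` inclusive (default U=100, D=50, length 151); on the '−' strand
the window is reverse-complemented so sequences are always reported in sense
orientation with the anchor at index U. Windows overrunning a contig are
skipped and counted (padding would distort per-position n).

## Step-parameter profiling

A physical property is a map from k-mer "steps" (k=2 or 4) to real values.
A sequence of length L yields a chain of L−k+1 values with a 1-bp
frameshift. Conventions:

* the step value is assigned to the TSS-relative coordinate of the step's
  **first** base. The assignment convention is not determined by the
  underlying physics, so all profile features carry a ≤(k−1) bp right-shift
  ambiguity — material only for the k=4 rigidity table;
* lowercase is folded to uppercase before lookup; any step containing a
  non-ACGT character is missing (NaN) and reduces that position's n;
* units are labels only; no conversion is performed.

Aggregation computes, at every position spanned by at least one chain, the
mean and **sample** SD (n−1 denominator; recorded in the output header so
population-SD users can tell) over non-missing values. The variance uses a
two-pass algorithm: the one-pass sum-of-squares form loses ~8 significant
digits when SD ≪ |mean|, which is the normal regime for these tables.
Positions spanned by no chain are omitted; spanned positions whose values
are all missing keep their row with n=0 and NA mean, so positions are always
contiguous.

### Packaged tables

| property | k | units | source |
|---|---|---|---|
| duplex_free_energy | 2 | kcal/mol | unified nearest-neighbor ΔG°37 (SantaLucia 1998) |
| base_stacking_energy | 2 | kcal/mol | stacked-dimer energies (Ornstein et al. 1978) |
| deformability | 2 | dimensionless | protein-induced deformability (Olson et al. 1998) |
| rigidity | 4 | dimensionless | **synthetic stand-in** (see below) |
| zdna_as_energy | 2 | kcal/mol | **synthetic stand-in** (see below) |

The rigidity and Z-DNA(AS) source tables were not obtainable in this
offline build. Rather than fabricate attributed numbers, the package ships
clearly labelled stand-ins (`*.synthetic.tsv`): rigidity of a tetranucleotide
is the mean over its three dinucleotide steps of 10/deformability (a
physically sensible stiffness proxy that is reverse-complement symmetric by
construction); the Z-DNA table encodes the published qualitative ordering
(alternating purine–pyrimidine steps favored, CG lowest). All dinucleotide
tables satisfy value(step) = value(reverse-complement step), as any property
of the double helix must; this is enforced by tests. Tables are
configuration: any TSV following the documented schema can be substituted,
so correcting a stand-in requires no code change.

## CPE scanning and species classification

Element definitions (IUPAC consensus, canonical TSS-relative start,
tolerance) ship as an editable YAML; the defaults are the human Pol II set
BREu (SSRCGCC at −38), TATA (TATAWAWR at −31), BREd (RTDKKKK at −23), Inr
(BBCABW at −3, A at the TSS) and DPE (RGWYVT at +27), transcribed from the
standard core-promoter compilation with positions shifted to the TSS=0
convention. Choices made where the convention was open:

* the ±5 bp tolerance shifts the **whole consensus window**, not individual
  bases;
* scanning is sense-strand only;
* at most one best hit per element: minimal |shift|, ties to the upstream
  (negative) shift. All in-window matches are also exposed
  (`ScanResult.all_matches`) — planted-recovery tests operate at this level,
  because with a degenerate consensus like Inr an accidental background
  match at a smaller |shift| than the plant is not rare and is a legitimate
  match, not an error;
* an element whose search window extends beyond the extracted promoter is
  *unevaluable*; a promoter whose every element is unevaluable is excluded
  from species tabulation rather than mislabelled core-less;
* species labels are presence/absence only, elements ordered by canonical
  start (upstream first), `+`-joined; BREu and BREd stay distinct; a match
  counts whenever the extracted sequence covers it, even if it extends past
  a display window.

## Landmark detection

`locate_landmarks` operationalizes "distinctive profile sites": within the
TSS window (default [−5, +5]) and the upstream window (default [−35, −20],
bracketing −27) it reports the position maximizing |mean − baseline|, where
the baseline is the median of the mean over all positions outside both
windows and the noise scale is their median absolute deviation (MAD). A
landmark is *distinctive* when its magnitude exceeds 5×MAD. The MAD-based
threshold makes the flag scale-free across properties with very different
units; a flat profile has magnitude ≈ 0 and is never flagged.

## tRNA regions

The three regions are defined purely by their anchors — TSS (−50..0),
mature 5′ end (0..+30), discriminator base (−30..0), all endpoints
inclusive (51/31/31 nt) — and are never located by motif search, because
A–B spacing is irregular (introns, variable loop). The TSS base itself is
included in the upstream region (it is position 0 of that profile). The
representative TSS of a gene is the highest-TPM row, ties broken by
coordinate then contig, exactly like the highest-TIEScore rule for Pol II
promoters.

## Sequence logos

Relative-entropy logos: IC = Σ_b f_b log2(f_b/q_b) with 0·log 0 := 0,
uniform background by default (IC ∈ [0,2] bits), no small-sample correction
(intended n is thousands). Non-ACGT bases are tallied as "other" and
excluded from the frequency denominator rather than spread fractionally.
Rendering is matplotlib TextPath (no external logo package required).
Default window [−5, +5], configurable.

## The synthetic world

The generator emulates what the pipeline needs from real data and nothing
more:

* fixed-length windows (default 151 nt, anchor at 100 = U 100/D 50) with an
  i.i.d. background of configurable GC content (default 0.5);
* a species mixture (default {core-less 0.55, Inr 0.30, TATA+Inr 0.15},
  mirroring the observed majority-core-less, Inr-rich-minority structure of
  Pol II promoter sets); planted elements get a uniform shift in the
  configured jitter range (default ±5);
* **accidental background matches are not suppressed** — as in real
  genomes. Classification tests therefore compare observed species
  fractions against an expectation built from per-element accidental rates
  measured on a zero-plant control under element independence
  (`expected_species_fractions`). The independence approximation is mildly
  violated where a planted TATA overlaps the BREu/BREd search windows; the
  induced bias is bounded by mix_share × rate ≈ 0.01, well inside the
  3-binomial-SE test band at n = 2000 (measured |z| ≲ 1.3);
* elements are planted in label order, so species combining elements with
  overlapping jitter windows (among BREu/TATA/BREd) can overwrite each
  other's bases; recovery tests use species with disjoint windows;
* tRNA genes: one 400-nt contig per gene, random strand, TSS fixed 80 nt
  into the sense neighborhood, 4–12 nt leader to the mature 5′ end, A-box
  (TGGCNNAGTGG) at +7 from the mature 5′ end, 20–40 nt A–B spacer, B-box
  (GGTTCGANNCC) ending 3–12 nt before the discriminator — offsets chosen so
  both boxes always fall inside their profiled windows, with spacing
  variability retained;
* randomness: sequence i draws from `numpy.random.default_rng([seed, i])`,
  so growing n never reshuffles earlier sequences and runs are
  byte-reproducible.

What a green test does **not** establish: real promoters are not i.i.d.
background (CpG islands, GC skew, nucleosome-positioning signals), element
co-occurrence is not independent, and real TSS atlases carry positional
uncertainty the generator does not model. The synthetic tests validate the
machinery (recovery, accounting, profile math, workflow shape), not the
biology.

## Degenerate inputs and numerical choices

* empty FASTA, duplicate contigs, malformed BED rows, incomplete step
  tables: hard errors naming the offending record;
* contig-edge windows: skipped, counted, never padded;
* score ties in representative-TSS selection: coordinate then contig name;
* profile TSVs serialize NaN as "NA" and floats at repr precision, so the
  paired reader round-trips losslessly and reruns are byte-identical;
* oracle-equivalence tests require agreement with naive reimplementations
  to 1e-9 (profiling) and exactness (chain values).

## Known limitations

* Rigidity and Z-DNA(AS) tables are stand-ins (above); profiles computed
  from them are internally consistent but not literature-attributable.
* Consensus matching only — no PWM scoring, no motif discovery.
* No smoothing or significance testing of profile differences between
  groups; comparisons are by inspection, plus the landmark detector.
* No liftover, CAGE clustering, TIEScore/TPM computation, or DHS/context
  classification; these arrive as input metadata.
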