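# Methods

## Synthetic microscopy fields

A field is a pair of 2-D channels (nuclear, reporter) of 16-bit-range
intensities. Cells are disks of uniform cytoplasmic intensity (default
500 a.u.) with a concentric nuclear disk that is bright in the nuclear
channel (2000 a.u.) and slightly darker than cytoplasm in the reporter
channel (350 a.u.) — the contrast the propagation segmentation relies on.
Puncta are hard-edged filled ellipses (focus intensity 2000 a.u.) placed
in the cytoplasmic annulus of their cell, pairwise separated so the
ground truth is unambiguous. The noiseless composite is blurred with a
σ = 0.5 px Gaussian to emulate optics — small enough that the analytic
rasterized pixel count remains the usable truth area — and i.i.d.
Gaussian read noise (default σ = 50 a.u., i.e. focus SNR ≈ 30 over
cytoplasm) is added. Defaults emulate a 20× field of adherent human
cells: 512×512 px, 20 cells, nuclei 8 ± 1 px radius, cell bodies
20 ± 2 px, foci 2.5 ± 0.4 px with Poisson(2.5) foci per cell. The foci
count/size distribution under stress is not an empirical claim; it is a
free parameter chosen to look like typical arsenite-stressed fields.

Time courses re-render the same geometry at each timepoint (default
every 30 min for 10 h); foci exist only between `condensation_onset`
(30 min) and `condensation_offset` (150 min), emulating transient
granule assembly and disassembly under acute stress. Read noise is
redrawn per frame; cell positions persist. What the generator does *not*
emulate: point-spread-function optics, photobleaching, cell motility,
overlapping/touching cells, or 3-D structure. Passing recovery tests
therefore demonstrates correctness of the measurement pipeline, not
robustness to crowded or low-SNR real data.

## Segmentation pipeline

Intensities may be rescaled by a constant factor. Nuclei: Otsu threshold
of the nuclear channel, hole filling, 8-connected labeling, area gate
(default 50–5000 px²). The Otsu threshold is computed on an explicit
histogram (256 equal bins over the data range unless a histogram is
supplied) by maximizing the between-class variance; exact ties resolve
to the lowest candidate. Cells: seeded watershed from the nuclear labels
over a cost surface `grad + λ·dist`, where `grad` is the normalized
Sobel gradient magnitude of the reporter channel, `dist` the Euclidean
distance from the seeds, and λ (default 0.05) the propagation
regularization — λ→∞ gives a purely geometric nearest-seed partition,
λ→0 a purely intensity-guided one. Foreground is the Otsu threshold of
the reporter channel; each cell contains exactly one nucleus by
construction. Foci: white top-hat with a disk structuring element
(default radius 5 px ≈ 2× the expected focus radius) suppresses
structures larger than the element; the enhanced image is thresholded by
Otsu or a manual value, components below 4 px² are dropped. In Otsu
mode, if more than 20 % of pixels exceed the threshold the field is
declared focus-free — a flat top-hat image only offers its noise floor
to threshold. Foci with moment eccentricity ≥ 0.875 (strict keep-below)
are discarded as segmentation artifacts.

Per cell: a focus belongs to the cell label under its intensity-weighted
centroid (label 0 = unassigned, tallied separately). A cell "has foci"
when its retained-focus count is ≥ 1; this cutoff is a package
convention. Condition summaries report, per replicate, the percentage of
cells with foci and the per-cell means of foci count and total area,
then mean ± SEM (sd/√N) across replicate-level values; QC flags mark
replicates with < 100 cells and conditions with < 3 replicates. Group
comparisons use a two-sided Mann–Whitney test on pooled per-cell values
against a reference condition (an interpretation — rank tests are the
standard choice for skewed per-cell metrics), with the usual star tiers
at 0.05/0.01/0.001/0.0001. The expression-matching control flags
conditions whose median reporter intensity deviates from the reference
median by strictly more than 25 %.

Known limitations: nuclei closer than the threshold bridge merge into
one object; granules are not tracked between frames; everything is 2-D.

## Count model and testing

`generate_counts` draws NB counts with mean s_s·q_g·2^LFC(g,s) and a
single dispersion α (variance μ + αμ²). The design is two assays (RNA,
RIBO) × two conditions × n replicates (default 3); size factors are
uniform in [0.7, 1.4] unless given. Planted classes set the treated-
condition LFCs: TE ±e on RIBO only, BUFFERING ±e on RNA only,
RNA_ABUNDANCE ±e on both, RIBO_OCP ±e on RIBO with ±e/2 on RNA (a pure
RIBO-only change would be generatively identical to TE). The noiseless
mean matrix is returned alongside the truth table.

Size factors are median-of-ratios over genes positive in all samples
(they agree with pydeseq2 to machine precision). Dispersions: gene-wise
method-of-moments on normalized counts pooled within design cells, a
lowess trend of log α on log mean (span 0.3) over genes with positive
gene-wise estimates, log-space shrinkage toward the trend (gene-wise
weight 0.35), and a floor at the trend. Two small-sample calibrations
are deliberate. First, lowess tracks the *median* of the gene-wise
estimates, which for a chi-square-driven variance at d residual df sits
a factor median(χ²_d)/d (≈ 0.84 at d = 4) below the mean, so the fitted
trend is divided by that factor. Second, at 2–4 replicates the
gene-wise estimate is noisy downward and plugging it into a Wald test
inflates the size; flooring at the (corrected) trend restores the
nominal level — empirically ≈ 0.044 at nominal 0.05 for 3 vs 3,
α = 0.1, versus ≈ 0.07 without these guards. α is never below 10⁻⁸;
all-zero genes get NaN and are excluded.

Wald tests fit per-gene NB GLMs (log link, log size-factor offsets) with
the plug-in dispersion; the statistic is β̂/SE against the standard
normal, two-sided, BH-adjusted over testable genes. baseMean is the mean
of normalized counts. Fold-change shrinkage is a normal-prior MAP:
β̂·σ²/(σ²+SE²), with σ moment-matched from the observed LFC/SE
distribution — a deliberate simplification of heavier-tailed priors; it
preserves sign, never increases magnitude, and leaves p-values alone.

TE is the condition × assay interaction of one NB model per gene over
all samples of both assays, with assay-specific size factors and one
shared dispersion per gene (the simplification used by interaction-based
TE tools; it stabilizes small-n fits). Swapping the assay labels negates
the interaction exactly (the 2×2 cell-mean parameterization is
saturated).

### Classification rules

Genes must pass RNA baseMean > 20 **and** Ribo baseMean > 20. Flags,
set independently:

| flag | rule |
|---|---|
| buffering up/down | RNA padj < 0.01, RNA LFC ≷ 0, Ribo padj ≥ 0.05 |
| ribo ocp up/down | Ribo padj < 0.05, Ribo LFC ≷ 0 |
| RNA abundance up/down | RNA and Ribo padj < 0.05, concordant LFC signs |
| TE up/down | TE padj < 0.05, TE LFC ≷ 0 |

Buffering additionally requires a non-significant Ribo change because
that is what "buffered" means: the mRNA moves, ribosome occupancy does
not. Discordant significant RNA/Ribo pairs keep no directional
RNA-abundance flag but are marked `discordant`. The canonical label
resolves multi-flag genes by precedence **RNA abundance > Buffering >
TE > Ribo ocp**. Buffering outranks TE by design: an RNA-only change
mathematically carries an opposite-sign TE interaction (TE ≈ Ribo −
RNA), so that TE signal is the buffering signature itself, not an
independent translational event; ranking TE first would relabel every
strongly buffered gene as TE. All flags are retained in the output so
other conventions can be applied.

## Enrichment

Rankings sort by (score desc, gene id asc); the tie rule is explicit
because the ES depends on order. The ES is the signed extremum of the
weighted KS running sum (hits weighted |score|^p normalized to 1,
default p = 1; misses 1/(N−K)); an exact |max| = |min| tie resolves
positive (tolerance 10⁻¹²). The null re-draws random same-size gene sets
(the only permutation a preranked list admits); p is one-sided within
same-signed null ESs, p = (1+#{|ES₀|≥|ES|, same sign})/(1+#same-sign) —
the fgsea convention, which keeps p ≥ 1/(n_perm+1) and uniform under the
null. NES divides by the mean |ES₀| of the same sign; ES and p, not NES,
are the comparable quantities across implementations. Default 10 000
permutations. Over-representation: upper-tail hypergeometric per term
against the background of genes with TPM strictly above 1 in at least
one sample; BH across terms, significance at padj < 0.05.

## Melt curves

The generator produces logistic curves on the instrument grid
(25→95 °C, 0.2 °C steps, 351 points), default amplitude 100 a.u.,
baseline 10 a.u., steepness 1.0 /°C (a 10–90 % transition of ≈ 4.4 °C,
typical of small-domain DSF), plus Gaussian noise. Tm is located by
smoothing the fluorescence with a centered moving average (odd window,
default 5 points ≈ 1 °C), taking the central-difference first
derivative, and reporting the temperature of its maximum; curves whose
derivative never exceeds zero raise a no-transition error. With 2 %
noise and the 5-point window the mean absolute recovery error over 50
simulated curves is ≈ 0.25 °C; individual worst cases can reach ≈ 1 °C
because the derivative of a logistic is flat near its peak — a
fundamental limit of argmax-on-grid estimation, which is why the
recovery guarantee is stated as a mean.

## Orchestration and reproducibility

`run_pipeline` executes selected stages in dependency order from one
YAML config whose defaults carry the standard thresholds (eccentricity
0.875; baseMean 20; padj 0.01/0.05/0.05; TPM > 1; 10 000 permutations),
logs every threshold actually applied, and writes a manifest with the
seed, parameters, per-stage row counts and a SHA-256 content hash over
all outputs. One global seed fans out to per-stage children through a
SeedSequence keyed on (seed, CRC-32 of the stage name), so stages rerun
independently yet reproducibly; reruns are byte-identical.

## Validation scales

The test suite and `scripts/acceptance.py` run at sizes chosen to make
every property measurable with comfortable statistical margins while
keeping a full run in well under a minute per stage: 10 fields × 20
cells for segmentation recovery; 2000 genes, 3 vs 3 at dispersion 0.1
for the type-I check; 2000 genes at baseline mean 200, dispersion 0.05,
effect |LFC| = 2 for class recovery; 800 genes, 8 replicates at
dispersion 0.001 for the TE-null bias probe (sized so the interaction SE
≈ 0.08 log2 units puts the ±0.2 band at 2.5 SE — the probe isolates
estimator bias, which sampling noise would otherwise swamp); 200 × 200
permutations for p-uniformity; 50 curves for Tm recovery; and a
2-field / 400-gene double run for byte-level determinism.
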