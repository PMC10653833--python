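# polarsig

Quantification of polar fluorescent protein clusters in rod-shaped bacteria.

Many envelope-spanning machines — the type IVa pilus machine and its
outer-membrane secretin are the motivating case — assemble at the cell
poles, and fluorescence microscopy of tagged components shows faint foci at
one pole, both poles, or the division site. Deciding *objectively* whether a
cell has a cluster, where it is, and when in the cell cycle it appears
requires a reproducible statistic rather than visual judgement. `polarsig`
implements such a pipeline for single-channel epifluorescence images of
segmented rod-shaped cells, together with a synthetic-microscopy generator
that provides ground truth for every stage.

## The statistic at its core

For a cell subdivided into ordered axial segments (an Oufti-style mesh), let
`m_i` be the strongest pixel intensity in segment `i` after background
correction, and normalize to the cell maximum:

    v_i = m_i / max_j m_j            (so v ∈ [0,1]^n, max v = 1)

The cell **has a cluster** iff

    #{ i : v_i > 0.75 } / n  <  0.10

i.e. fewer than 10% of the per-segment maxima lie above 0.75 of the cell
maximum — an intense and *narrow* peak. A diffusely bright envelope
normalizes to a flat profile near 1 (negative); a faint focus over dimmer
envelope signal yields a narrow supra-threshold run (positive). Both
inequalities are strict; the verdict is invariant to rescaling the image.

On top of this criterion the package provides:

* **Pattern classification** — clusters at relative position < 0.1 / > 0.9
  are polar; both poles = bipolar, one pole = unipolar; an independent
  mid-cell flag for clusters in [0.40, 0.60]; populations summarized as
  percentages, stratified into short (< 6.5 µm) and long (≥ 6.5 µm) cells.
* **Demograph-style profiles** — per-cell normalized intensity along
  relative cell length (0 = brightest pole, or 0 = old pole given lineage),
  pooled into population mean ± SD on a common 100-bin grid; plus the polar
  fraction of total cellular fluorescence.
* **Division-relative timing** — overlap-based lineage tracking; completion
  of cytokinesis (the first frame with two daughter masks) defines t = 0;
  cluster appearance offset (negative when the focus predates division at
  mid-cell) and cluster lifetime with movie-end censoring.
* **Synthetic data** — spherocylindrical cells with membrane-weighted
  signal, diffraction-limited membrane foci, Poisson + read noise, growth,
  constriction and division, configurable pattern mixtures and event-time
  laws, and a division-blocked (cephalexin) mode. Images are 16-bit TIFF,
  meshes a plain-text format, truth TSV.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a 200-cell snapshot with a known 60/25/15 bipolar/unipolar/none
mixture and analyze it in one step:

```sh
cat > sim.yaml <<'YAML'
simulate:
  kind: snapshot
  n_cells: 200
sim:
  pattern_probs: {bipolar: 0.6, unipolar: 0.25, midcell: 0.0, none: 0.15}
YAML
polarsig simulate --config sim.yaml --out demo --seed 7
cat demo/report.txt
```

prints

```
polarsig 0.1.0 report
config=8b65ae7758e99e7e seed=7

cells analyzed: 200
  [all] n=200  unipolar 27.5%  bipolar 57.0%  no cluster 15.5%  mid-cell 0.0%
  [short] n=154  unipolar 27.3%  bipolar 55.8%  no cluster 16.9%  mid-cell 0.0%
  [long] n=46  unipolar 28.3%  bipolar 60.9%  no cluster 10.9%  mid-cell 0.0%
```

The recovered percentages (57.0 / 27.5 / 15.5) sit within sampling error of
the generating mixture. `demo/` also contains the rendered image stack
(`images.tif`), the meshes, per-cell verdicts (`calls.tsv`: length, length
class, cluster positions, pattern, mid-cell flag), per-cell and population
profiles, and the generator truth for comparison. The same pipeline runs on
real data given a TIFF and a mesh file or label image
(`polarsig detect --images X.tif --meshes M.txt --out OUT`), and
`polarsig run --config cfg.yaml` adds tracking and timing for movies
(`timing.tsv`: t0 frame, appearance offset in minutes, lifetime, censoring).

In the library API the same analysis reads:

```python
import polarsig as pk

params = pk.DetectionParams()          # 0.75 / 10% / windows / 6.5 µm split
frame, meshes, truth = pk.simulate_snapshot(200, pk.SimParams(seed=7))
corr = pk.background_correct(frame, meshes)
calls = [pk.call_cell(m, corr, params) for m in meshes]
print(pk.summarize_population(calls, params))
```

## Limitations

Straight cells only (no curved-axis coordinates); no point-spread-function
optics or segmentation-error simulation; no sub-pixel spot fitting, no
multi-channel colocalization, no drift or motility correction.
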