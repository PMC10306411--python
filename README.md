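# pepc

Kinetics separation for time-resolved X-ray solution scattering
(liquidography) difference data, built around projection to extract the
perpendicular component (PEPC): per time delay, the components of
ΔS(q, t) parallel to a set of *known* curves — the solvent heating
differentials (∂S/∂T)ρ and (∂S/∂ρ)T, or the curves of already-identified
intermediates — are removed by orthogonal projection. The residual carries
the intact kinetics of everything *outside* that known span, so the solute
kinetics can be read off without any prior knowledge of the molecular
structures involved.

Intended users: people analyzing pump–probe solution scattering data
(synchrotron or XFEL), and anyone who needs to strip the variable-dependent
contribution of a known spectral component from a matrix-valued dataset.

## The model

A difference scattering matrix decomposes as

    ΔS(q, t) = (1/R) Σ_k f_k(t) · SADS_k(q)
             + ΔT(t) · (∂S/∂T)ρ + Δρ(t) · (∂S/∂ρ)T ,

with R the solvent:solute number ratio, f_k(t) the molar fraction of
species k, and SADS_k(q) its species-associated difference scattering curve
(solute plus solvation cage). Given trivial components {trv_1 … trv_m}, the
PEPC residual is the least-squares projection residual per delay:

    ΔS(q, t)_PEPC = ΔS(q, t) − Σ_i w_LS,i(t) · trv_i(q) ,

orthogonal to every trv_i, unique even for a rank-deficient trivial set,
and free of the trivial components' kinetics (ΔT, Δρ, known-species
fractions) while every f_k(t) outside the span survives unchanged.

Downstream, the toolkit provides: SVD with autocorrelation-based rank
selection; global fitting of the significant right singular vectors with
exponentials sharing common time constants, each convolved analytically
with a Gaussian IRF; kinetics-constrained extraction of SADS under a
first-order model (Bateman chains or arbitrary rate matrices);
correction of the projection-induced SADS distortion
(SADS_corr = SADS_PEPC + Σ_i α_i·trv_i, with α solved linearly) and
χ²-based discrimination of candidate structures via a toy Debye
calculator; per-delay reconstruction of ΔT(t) and Δρ(t) from the
solute-subtracted data; and a null-hypothesis residual test for hidden
reaction intermediates. A forward simulator generates complete datasets
with full ground truth so every stage is testable at desk scale.

## Worked example

Simulate a three-species sequential photocycle (time constants 1.7 ps,
1.0 ns, 114 ns; Gaussian IRF of 0.48 ps FWHM) in a water-like solvent at
5% noise, then recover the kinetics with no knowledge of the solute:

```sh
$ cat sim.yaml
scenario: gtc_like
noise_sigma: 0.05
seed: 1
$ pepc simulate --config sim.yaml --out sim/
$ pepc pepc --data sim/matrix.tsv \
    --trivial sim/basis_dS_dT_rho.tsv --trivial sim/basis_dS_drho_T.tsv \
    --out pepc.tsv --weights-out weights.tsv
trivial rank 2; residual written to pepc.tsv
$ pepc svd --data pepc.tsv --out svd/
64 components; 3 significant at default thresholds
$ pepc fitrsv --data pepc.tsv --k 3 --nexp 3 --irf 0.48 --out fit.json
taus (ps): 1.64163, 991.657, 113653
```

After removing both solvent differentials, the rank diagnostics report
exactly three significant components (three solute species), and the global
fit of the three right singular vectors returns 1.64 ps, 992 ps and
113.7 ns — the generating constants 1.7 ps / 1000 ps / 114 000 ps recovered
within a few percent at this noise level (`fit.json` also carries standard
errors: ±0.04 ps, ±27 ps, ±4.0 ns). The null test on the raw matrix,

```sh
$ pepc test-null --data sim/matrix.tsv --trivial sim/basis_dS_dT_rho.tsv \
    --trivial sim/basis_dS_drho_T.tsv --out null.json
signal_remains
```

correctly reports that the two solvent curves alone do not explain the
data. `pepc run --config analysis.yaml` chains all stages (including SADS
extraction, correction and hydrodynamics) and writes a `summary.json`;
`pepc split` and `pepc kca`, `pepc correct`, `pepc rank`, `pepc hydro`
expose the individual stages.

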