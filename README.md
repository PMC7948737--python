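# glycokinetics

Bisubstrate enzyme-kinetics and SPR binding-affinity analysis for
glycosyltransferase assays, built around the kinetic characterization of
B3GNT2 — the β1,3-N-acetylglucosaminyltransferase that extends
poly-N-acetyl-lactosamine by transferring GlcNAc from UDP-GlcNAc (donor, A)
onto LacNAc (acceptor, B).

It is written for enzymologists who have (or want to simulate) three kinds of
raw data — luminescent UDP-release progress curves on a donor × acceptor
concentration grid, SPR sensorgram families, and SEC calibration tables — and
want the full inferential chain: initial-velocity extraction, mechanism
discrimination, global rate-law fitting with uncertainties, and 1:1 affinity
fits.

## The model

Initial velocities of a two-substrate reaction are fitted to the
rapid-equilibrium random-order sequential rate law

```
         k_cat [E] [A][B]
v = ─────────────────────────────────────────
    α K_A K_B + α K_A [B] + α K_B [A] + [A][B]
```

where `K_A`, `K_B` are the dissociation constants of the binary
enzyme–substrate complexes, and `α` is the cooperativity factor: `α < 1`
means each substrate tightens the other's binding in the ternary complex
(`1/α` is the fold-enhancement). Two alternative mechanisms are carried along
for comparison — ping-pong bi-bi (`v = k_cat[E][A][B]/(K_A[B] + K_B[A] +
[A][B])`, parallel double-reciprocal lines) and rapid-equilibrium
compulsory-order with A first (`v = k_cat[E][A][B]/(K_AK_B + K_B[A] +
[A][B])`, lines meeting on the 1/v axis). Mechanism calls combine
extra-sum-of-squares F-tests on the Lineweaver–Burk line families with AICc
comparison of the three global fits in velocity space.

SPR sensorgrams are double-referenced, solvent-corrected, reduced to
equilibrium responses, and fitted to the 1:1 Langmuir isotherm
`Req = Rmax·C/(K_D + C) + offset` (steady state) and to the global 1:1
kinetic model with a single shared `Rmax` (`K_D = koff/kon`).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
generated under the published experimental design (5×5 grid: UDP-GlcNAc
62–1000 μM × LacNAc 1.56–25 mM at 1.25 nM enzyme; SPR 1:3 series 2.5–200 μM):

```sh
python analysis/01_simulate_assays.py --seed 0
python analysis/02_extract_velocities.py
python analysis/03_mechanism_inference.py
python analysis/04_spr_affinity.py
python analysis/05_sec_mw.py
```

which prints (seed 0):

```
standard curve: 1001.2 RLU/uM (r^2 = 0.99997)
extracted 25 initial velocities -> results/velocities_extracted.csv
parallel_vs_intersecting: intersecting (F = 5.35e+03, p = 1.86e-23)
yaxis_intersection: off_y_axis (F = 692, p = 8.23e-17)
selected mechanism: random_rapid_equilibrium
  k_cat (min^-1) = 35.26  [95% CI 34.96, 35.85]
  K_A (uM) = 235.9  [95% CI 222, 256.1]
  K_B (uM) = 9181  [95% CI 8507, 1.009e+04]
  alpha = 0.2191  [95% CI 0.1929, 0.2444]
  1/alpha = 4.56 -> substrates held ~5-fold more tightly in the ternary complex
udp_glcnac: KD = 140 +/- 0.35 uM, Rmax = 40 RU, saturation at top = 0.59
udp: KD = 260.2 +/- 1.5 uM, Rmax = 40 RU, saturation at top = 0.43 (nonsaturating: ...)
lacnac: KD = 9094 +/- 1.3e+04 uM, ... saturation at top = 0.02 (nonsaturating: ...)
enzyme peak at 8.31 ml -> ~84 kDa (1.99x the 42 kDa monomer: consistent with a dimer)
```

Reading the output: the intersecting, off-axis reciprocal lines rule out both
the ping-pong and the compulsory-order mechanisms; the AICc-selected
random-order fit recovers the generating constants (truth: k_cat 35.8 min⁻¹,
K_A 216 μM, K_B 8.99 mM, α 0.24) to within the noise of a single simulated
plate; the weak acceptor-like SPR scenario is correctly flagged as too far
from saturation for a reliable K_D; and the SEC estimate reads the enzyme
peak as a dimer.

A `glycokinetics` command-line tool exposes the same steps
(`simulate`, `extract`, `discriminate`, `fit`, `spr`, `sec`, `report`).

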