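# cellspray

Predicting cell survival in droplet-based cell deposition (bio-printing by
spraying). When a cell-laden droplet hits a substrate, the carrier droplet
spreads, the suspended cell is flattened with it, and its membrane is
stretched; stretch it too far and the cell dies. `cellspray` implements an
analytical model of this impact chain, plus the surrounding tooling a
deposition experiment needs:

- **`cellspray.impact`** — the survival chain for a single cell in a single
  droplet: dimensionless impact numbers, droplet spreading, cell deformation
  with viscous cushioning by the carrier droplet, membrane-area expansion,
  and a piecewise-linear survival law.
- **`cellspray.ensemble`** — expected viability of a whole spray: per-droplet
  survival averaged over a measured or synthetic droplet spectrum, viability
  maps over the (diameter, velocity) plane, and parameter sweeps.
- **`cellspray.synth`** — a seeded synthetic spray generator (lognormal sizes,
  pressure/distance-dependent velocities) for studies when no measured
  spectrum is at hand.
- **`cellspray.imaging`** — synthetic double-pulse shadowgraphy: rendering of
  image pairs, droplet detection with focus gating, sizing, and two-frame
  velocimetry, so the full measure-then-predict pipeline can be exercised
  end to end on data with known ground truth.
- **`cellspray.cli`** — a `cellspray` command wrapping all of the above.

## The model in brief

For a cell of diameter $D_c$ inside a droplet of diameter $D_0$ impacting at
velocity $V_0$ on a substrate of stiffness $S \in [0,1]$:

1. **Soft substrates** are mapped to an equivalent hard-wall impact,
   $D_\mathrm{eff} = (2-S)\,D_0$, $V_\mathrm{eff} = (1+S)\,V_0/2$, with
   $S = \min(1,\,C_1 C_g)$ for gelatin mass fraction $C_g$ ($C_1 = 5$).
2. **Spreading** of drop and cell follows the capillary-regime law
   $D_\mathrm{max}/D = \mathrm{We}^{1/4}$, with a constant plateau below
   $\mathrm{We} = 5$, where $\mathrm{We} = \rho V^2 D / \sigma$.
3. **Deformation** of the flattened, volume-conserving oblate cell is
   $M_0 = (r^3-1)/(r^3+1)$ with $r = D_\mathrm{max}/D_c$ ($M_0 = 0$ sphere,
   $M_0 \to 1$ plane).
4. **Cushioning**: inside a droplet the cell deforms less than bare,
   $M = M_0^{\,k}$ with $k = 1 + C_0 (1 - D_c/D_\mathrm{eff}) / (1 + \mu_0/\mu_c)$
   ($C_0 = 5$) — larger droplets and less viscous inks protect better.
5. **Survival**: the cushioned deformation is converted back to a spreading
   diameter (clamped by the bare-cell and droplet extents), to an oblate
   surface area, and to the relative membrane-area expansion
   $\gamma = A_\mathrm{max}/(\pi D_c^2)$; survival is a linear ramp from
   $\eta = 1$ at $\gamma \le 1$ to $\eta = 0$ at $\gamma \ge 2$, crossing
   $\eta = 1/2$ at the critical expansion $\gamma_\mathrm{cr} = 1.5$.

Defaults model a myeloid cell ($D_c = 13\,\mu$m, $\mu_c = 12$ mPa·s,
$\rho_c = 1015$ kg/m³, $\sigma_c = 0.072$ N/m) in a water-like bio-ink. See
[docs/methods.md](docs/methods.md) for assumptions, parameter tables, and
limitations.

## Worked example

One droplet (39 µm at 10 m/s on a hard surface):

```console
$ cellspray predict --d0 39um --v0 10
we_cell          18.3264
re_cell          10.9958
we_droplet       54.1667
re_droplet       390
d_eff            3.9e-05
v_eff            10
d_max_droplet    0.000105803
d_max_cell_bare  2.68975e-05
m_bare           0.797107
m_cushioned      0.396727
d_max_cell       1.71979e-05
spheroid_height  7.42811e-06
area_max         6.07045e-10
gamma            1.14336
eta              0.856637
```

The cell's membrane is stretched to 1.14× its resting area, well below the
critical expansion of 1.5, so survival is high (η ≈ 0.86).

A full synthetic spray at the reference setting (0.4·10⁵ Pa, 30 mm nozzle
distance, water-like ink):

```console
$ cellspray ensemble --synthetic reference --n 10000 --seed 1
droplets          10000
excluded_fraction 0.0316
mean_viability    0.6317
```

About 3% of droplets are smaller than the cell and excluded; the expected
viability over the remaining spectrum is 63%. Other entry points:

```bash
cellspray sweep --parameter pressure --values 0.2,0.4,0.6,0.8,1.0 --out out/
cellspray map --n-d 50 --n-v 50 --out out/            # (D, V) viability map
cellspray simulate-spray --n 10000 --seed 1 --out spectrum.csv
cellspray ensemble --table spectrum.csv
cellspray detect --frame1 a.png --frame2 b.png --out measured.csv
```

Every command is deterministic given its configuration and seed, and commands
with `--out` write the resolved `run_config.yaml` beside their results.

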