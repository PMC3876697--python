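# snakedit

Scriptable, testable contour delineation for grayscale (medical-style)
images, combining three stages that are classically driven by a clinician
with a mouse:

1. **Initialization** — a closed Hermite cubic curve is fitted through a
   handful of user-supplied control points, producing a smooth digital
   boundary that interpolates every control point.
2. **Automatic refinement** — a snake (active contour) evolves that
   boundary by minimizing
   `E = ∫ ½(α|p′(s)|² + β|p″(s)|²) + E_ext(p(s)) ds`,
   where `p(s) = (x(s), y(s))` is the closed curve,
   `E_ext = −|∇(G_σ ∗ I)|²` is the Gaussian-gradient edge potential of the
   image `I`, and the Euler–Lagrange condition
   `α p″ − β p⁗ − ∇E_ext = 0` is solved by semi-implicit gradient descent.
3. **Multiscale correction** — uniformly arc-length-spaced control-point
   meshes are generated on the result at hierarchical levels (spacing
   halves at each level); declarative *edit scripts* move individual
   control points and the curve is re-fitted locally, repairing the
   snake's systematic errors at sharp, high-curvature boundary segments.

Converged contours can be carried forward slice by slice through a 3D
stack (`track`), so a volumetric region is delineated from a single
initialization. Synthetic phantoms (blurred/noisy disk, star, cone volume)
with exact ground-truth boundaries make every stage quantitatively
testable without clinical data or a GUI; every interactive action has a
file-based equivalent (control-point JSON, edit-script JSON).

Intended users: image-analysis researchers who need a reproducible,
scriptable stand-in for interactive boundary delineation, and anyone
teaching or benchmarking active-contour methods.

## Worked example

Delineate a noisy blurred disk phantom end to end from the shell:

```sh
snakedit phantom --shape disk --noise 0.02 --seed 7 --out-prefix disk
# wrote disk.tiff

# 12 control points on a circle of radius 66 around (127.5, 127.5):
snakedit fit init_cp.json init.json
# fitted 12 control points -> 120-point contour

snakedit segment disk.tiff init.json snake.json --resample-n 48
# converged=True n_iter=44 energy=3.51901

snakedit eval snake.json disk_truth.json --circle 127.5 127.5 60
# {"hausdorff_px": 3.7288994860064038, "mean_distance_px": 0.6807364418882672,
#  "mean_radial_error_px": 0.6806649139790889}
```

The snake converged in 44 of its 50 allowed iterations and sits on average
0.68 px from the true radius-60 boundary. (The point-set Hausdorff value
is dominated by the 7.9 px spacing between the 48 snake points against the
dense truth polyline, not by boundary error.) The same stages are
available as a library:

```python
import snakedit as sk

ph = sk.make_disk(noise=0.02, seed=7)
field = sk.external_energy(ph.image, sigma=2.0)
res = sk.evolve(init_contour, field, sk.SnakeParams())
print(res.converged, sk.mean_radial_error(res.contour, (127.5, 127.5), 60))
```

and as one pipeline (`snakedit run config.json`) that writes the contour
after every stage plus a manifest and the resolved configuration.

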