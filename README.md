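# spcdimer

Free-energy and dimer-topology analysis of transmembrane helix dimerization,
built around the biased-sampling strategy used to study surfactant protein C
(SP-C): two-dimensional umbrella sampling over a pair of interface dihedrals
(φ₁, φ₂) combined with well-tempered metadynamics on the monomer separation
*d*, reweighted into a single equilibrium ensemble.

SP-C is a 35-residue α-helical pulmonary surfactant protein whose functions
are increasingly tied to dimer and oligomer formation.  The questions this
pipeline answers are: how strongly do two helices associate in the membrane
plane (the bound/unbound free-energy difference), which dimer topologies do
they form (symmetry-aware clustering of the bound ensemble), and which
residues make up the dimerization interface (contact-probability maps and
the interface motif).

## What the package computes

Given per-window collective-variable time series (COLVAR-style text),
metadynamics hill logs (HILLS-style text) and the window manifest, the
pipeline:

1. reconstructs every window's static bias
   `B_w(x) = umbrella_w(φ₁, φ₂) + V_w(d) + wall(d)` from configuration and
   hill logs (final-bias approximation for the well-tempered bias, γ = 50);
2. solves the binless multistate (MBAR-type) equations

       w_i ∝ [ Σ_w N_w exp((f_w − B_w(x_i))/kT) ]⁻¹,
       f_w = −kT ln Σ_i w_i exp(−B_w(x_i)/kT),

   for one normalized statistical weight per frame;
3. projects the free energy onto any collective variable, e.g. the bound
   coordinate *d*min (minimum inter-monomer bead distance over the helical
   segment, residues 9–33; bound ⇔ *d*min ≤ 0.60 nm), and computes
   ΔF = −kT ln(W_bound/W_unbound);
4. clusters the bound dimers by average-linkage agglomerative clustering on
   the monomer-swap-symmetric superposed RMSD (the two monomers of a
   homodimer are indistinguishable), with per-cluster free energies,
   centroids, region-distance and crossing-angle distributions, residue
   contact-probability maps and the interface-motif report;
5. attaches Bayesian block-bootstrap errors (one block per window, Dirichlet
   weights, the full reweighting fixed point re-solved per replicate) to all
   weighted estimates.

Because the package contains no MD engine, a first-class synthetic-data
module generates complete campaigns from a *planted* analytic free-energy
surface: three Gaussian basins (one per dimer topology — parallel, inverted
V-shape, V-shape — realized by toy bead helices that reproduce the
topologies' region-distance and crossing-angle signatures), an
orientation-dependent steric core and a dissociated plateau, sampled by
per-window overdamped Langevin dynamics under the full bias stack.  Basin
depths are calibrated so the planted cluster free energies follow the
−10.4 / −5.0 / −2.4 kJ/mol pattern with a 10.14 kJ/mol total bound/unbound
difference, so every downstream estimate has an exactly known target.
See `docs/methods.md` for the model, assumptions and parameter choices.

## Worked example

```sh
python analysis/01_simulate_campaign.py     # ~5 min: 144-window campaign
python analysis/02_reweight_free_energy.py  # ~8 min: reweight + cluster + report
python analysis/03_cluster_topologies.py
python analysis/04_interface_motif.py
```

Output of a run with the default seed (1):

```
planted bound/unbound dF = -10.022 kJ/mol
recovered dF(bound-unbound) = -9.82 +/- 6.09 kJ/mol (planted -10.02 kJ/mol)
PMF minimum at d_min = 0.475 nm
PMF deviation from planted profile over the sampled range: max 0.90, mean 0.21 kJ/mol

dendrogram gap selects 3 clusters (analysis used 3)
topology        dF (kJ/mol)   <d_min> (nm)  members   weight
parallel        -9.53 +/- 8.51   0.472 +/- 0.019    357    0.873
inverted-V      -2.77 +/- 9.69   0.469 +/- 0.022     26    0.064
V               -1.68 +/- 9.12   0.501 +/- 0.023     17    0.042
stability order (most to least stable): parallel > inverted-V > V

parallel     top contact residues: L14, V18, V21, V25, G29, L32
interface motif: L14xxxVxxVxxxVxxxGxxL32
```

Reading this: the recovered association free energy (−9.82 kJ/mol, bound
favored) matches the planted −10.02 kJ/mol; the free-energy profile along
*d*min has its bound minimum at 0.475 nm and tracks the planted profile
within 0.2 kJ/mol on average; the dendrogram cleanly separates the three
planted dimer topologies with the correct stability ordering; and the
interface of the most stable (parallel) topology is the expected
valine/leucine face culminating in the small-residue pattern around
V21/V25/G29.  The bootstrap error bars on cluster free energies are
conservative at this scale — the bound-state weight is carried by a handful
of umbrella windows, so one-block-per-window resampling disperses strongly
(seed-to-seed scatter of ΔF is ~0.6 kJ/mol).

The same machinery is scriptable (`spcdimer run --help`) and importable
(`spcdimer.pipeline.run_pipeline`, or the individual modules
`topology`, `bias`, `synthetic`, `reweight`, `bootstrap`, `ensemble`).

## Layout

    src/spcdimer/      library: geometry/CVs, bias reconstruction, toy
                       sampler + planted surface, reweighting, bootstrap,
                       clustering/descriptors, pipeline + CLI
    analysis/          numbered narrative drivers (simulate -> reweight ->
                       cluster -> motif), writing under results/
    scripts/           acceptance recomputation
    tests/             pytest suite incl. planted-recovery acceptance checks
    docs/methods.md    model, assumptions, parameter choices, limitations
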