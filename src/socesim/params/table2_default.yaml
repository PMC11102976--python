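# Default SOCE model parameter set (single-cell calcium simulations).
# Units: concentrations µM, time s, volumes L, lengths as noted, conductance S.
geometry:
  cell_volume: 1670.0          # µm³
  cytosol_volume: 1.1002e-12   # L
  er_volume: 8.35e-14          # L  (= cell_volume/20, in litres)
  junction_diameter: 100.0     # nm
  junction_height: 10.0        # nm
  n_junctions: 150
  diffusion_distance: 0.350    # µm
ca_ext: 1800.0                 # µM
temperature: 273.0             # K
z_ca: 2.0
membrane_potential: 5.0        # mV (fixed for SOCE-only runs)
diffusion_coefficient: 220.0   # µm²/s
ca_er_ref: 250.0               # µM, initial ER level normalizing release fluxes
crac:
  n_s: 3.0
  f_s: 6.663e-6                # 1/(µM³·s)
  b_s: 2.525                   # 1/s
  f_o: 1.226                   # 1/(µM·s)
  b_o: 0.06774                 # 1/s
  total_stim1: 1.0
  total_orai1: 1.0
  g_crac: 24.0e-15             # S
  n_crac_per_junction: 5.0
serca:
  R_serca: 100.0               # µM/s
  K_serca: 0.12                # µM
  I_serca: 0.025               # 1/µM
  hill: 1.0
pmca:
  R_pmca: 38.0                 # µM/s
  K_pmca: 0.9                  # µM
  hill: 2.0
leak:
  R_leak: 0.002                # 1/s
ip3r:
  R_ip3r: 0.18                 # µM/s
  k1: 0.64                     # 1/(µM·s)
  km1: 0.04                    # 1/s
  k2: 37.4
  km2: 1.4
  k3: 0.11
  km3: 29.8
  k4: 4.0
  km4: 0.54
  L1: 0.12                     # µM
  L3: 0.025                    # µM
  L5: 54.7                     # µM
  j2: 1.7                      # 1/s
  jm2: 0.8                     # 1/s
  j4: 1.7                      # 1/(µM·s)
  jm4: 2.5                     # 1/(µM·s)
  j6: 4707.0                   # 1/s
  jm6: 11.4                    # 1/s
ryr:
  R_ryr: 200.0                 # µM/s
  k2: 0.045                    # 1/(µM²·s)
  km2: 60.0                    # 1/s
  k4: 0.47                     # 1/(µM·s)
  km4: 5.0                     # 1/s
  k6: 0.3                      # 1/(µM·s)
  k11: 0.0045                  # 1/(µM²·s)
  Kd1: 1000.0                  # µM
  Kd3: 10000.0                 # µM
  Kd8: 638.3                   # µM
  csq_coupling: true
ip3:
  R_ip_ca: 2.8                 # µM/s
  K_ca_m: 1.1                  # µM
  R_ip_d: 1.0                  # 1/s
  ip3_rest: 0.25               # µM
buffer_cyt:
  k_on: 100.0                  # 1/(µM·s)
  k_off: 500.0                 # 1/s
  b_total: 660.0               # µM
buffer_csq:
  k_on: 100.0                  # 1/(µM·s)
  k_off: 65000.0               # 1/s
  csq_total: 14.0              # µM
  k_d: 638.0                   # µM (printed; kinetics use k_off/k_on = 650)
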