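# IODP Site U1325 (Cascadia margin) site preset.
# 2.5 m interval, centered 5 cm sand bed, buried at 0.19 mm/yr for 1.2 Myr.
name = u1325

# --- column geometry / lithology -------------------------------------------
domain_length_m = 2.5
sand_thickness_m = 0.05
dz_m = 0.005
n_sand_cells_cm3 = 1.0e9
n_mud_cells_cm3 = 1.0e6
poc_mud_wt_pct = 0.5
porosity = 0.5
grain_density_g_cm3 = 2.65
mud_profile_enabled = false

# --- kinetics ---------------------------------------------------------------
K_eh_per_mM_s = 1.99526231496888e-13    # 10^-12.7
K_fm_per_cell_s = 1.0e-23
K_m_per_cell_s = 1.0e-23
beta = 0.01
E0_mM = 0.5
lambda_half_yr = 1.0e4
epsilon = 0.0115
gamma_ch4 = 0.5

# --- transport --------------------------------------------------------------
D_hmw_m2_s = 5.0e-11
D_lmw_m2_s = 1.0e-10
D_enz_m2_s = 2.5e-11
D_ch4_m2_s = 4.4e-10

# --- burial and solubility --------------------------------------------------
sed_rate_mm_yr = 0.19
d0_m = 0.0
sol_form = linear
sol_c_ref_mM = 118.0
sol_d_ref_m = 0.0
sol_d_scale_m = 2.0e4
sol_mud_multiplier = 1.05
bghsz_depth_m = 245.0

# --- discretization / outputs ----------------------------------------------
dt_yr = 20.0
t_end_yr = 1.2e6
snapshot_times_yr = 0,3.0e5,6.0e5,9.0e5,1.2e6
series_interval_yr = 2000.0
occupancy = true
theta = 1.0
s_hfz = 0.01
s_top = 0.05
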