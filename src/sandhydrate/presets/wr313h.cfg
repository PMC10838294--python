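# Walker Ridge 313-H (Gulf of Mexico) site preset.
# 20 m interval, centered 3 m sand bed, buried at 1 mm/yr for 300 kyr.
name = wr313h

# --- column geometry / lithology -------------------------------------------
domain_length_m = 20.0
sand_thickness_m = 3.0
dz_m = 0.1
n_sand_cells_cm3 = 1.0e9        # cells per cm3 bulk sediment
n_mud_cells_cm3 = 1.0e6
poc_mud_wt_pct = 0.5            # labile POC, % of grain mass
porosity = 0.5
grain_density_g_cm3 = 2.65
mud_profile_enabled = false

# --- kinetics ---------------------------------------------------------------
K_eh_per_mM_s = 2.51188643150958e-13    # 10^-12.6, per mM enzyme per s
K_fm_per_cell_s = 3.16227766016838e-22  # 10^-21.5, per (cell/m3 fluid) per s
K_m_per_cell_s = 3.16227766016838e-22   # tied to K_fm
beta = 0.01
E0_mM = 0.5
lambda_half_yr = 1.0e4          # extracellular enzyme half-life
epsilon = 0.04                  # enzyme yield of fermentation
gamma_ch4 = 0.5                 # CH4 fraction of methanogenesis carbon

# --- transport --------------------------------------------------------------
D_hmw_m2_s = 5.0e-11
D_lmw_m2_s = 1.0e-10
D_enz_m2_s = 2.5e-11
D_ch4_m2_s = 1.0e-10

# --- burial and solubility --------------------------------------------------
sed_rate_mm_yr = 1.0
d0_m = 0.0
sol_form = linear
sol_c_ref_mM = 100.0             # C_eq at the seafloor
sol_d_ref_m = 0.0
sol_d_scale_m = 500.0
sol_mud_multiplier = 1.004
bghsz_depth_m = 900.0

# --- discretization / outputs ----------------------------------------------
dt_yr = 10.0
t_end_yr = 3.0e5
snapshot_times_yr = 0,3.0e4,6.0e4,1.0e5,1.5e5,2.0e5,2.5e5,2.9e5,3.0e5
series_interval_yr = 500.0
occupancy = true
theta = 0.5
s_hfz = 0.01
s_top = 0.05
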