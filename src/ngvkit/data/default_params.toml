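# Default parameter file for the compartmental NGV energy-metabolism model.
#
# Units: concentrations mM (cAMP in uM), time s. Rate constants carry the
# units implied by their rate law. All values are physiologically plausible
# placeholders chosen so that the resting state below is a balance point of
# the network; every value can be overridden from a user TOML file.
#
# Fluxes are expressed in the frame of the compartment named first in the
# flux symbol's receiving convention (see metabolic_core.fluxes docstring).

[pools]
A_tot = 2.5     # adenine pool, mM (ATP + ADP)
Nc_tot = 0.5    # cytosolic NAD pool, mM
Nm_tot = 0.5    # mitochondrial NAD pool, mM
C_tot = 10.0    # creatine pool, mM (PCr + Cr)

[glucose_transport]
T_glut_ce = 0.09375      # capillary -> ECS GLUT Vmax, mM/s (ECS frame)
T_glut_en = 0.03333333333333333   # ECS -> neuron
T_glut_ea = 0.0525       # ECS -> astrocyte
K_glut = 3.0             # GLUT affinity, mM

[lactate_transport]
T_mct_n = 0.044          # neuron MCT Vmax, mM/s (cell frame, + = export)
T_mct_a = 0.2112         # astrocyte MCT Vmax
T_mct_ec = 0.07663333333333333    # ECS <-> capillary MCT
K_mct = 1.0              # MCT affinity, mM

[glycolysis]
k_hk = 0.12490363636363638   # hexokinase-PFK lump, 1/s
K_I_atp = 1.0            # ATP Hill inhibition constant, mM
n_H = 4.0                # Hill coefficient of ATP inhibition
K_hk_atp = 0.05          # substrate-ATP affinity of the HK lump, mM
k_pk = 0.06073858114674442    # downstream glycolysis lump, 1/s

[ldh]
k_ldh_f_n = 20.0         # mass action forward (PYR + NADHc -> LAC), 1/(mM s)
k_ldh_r_n = 0.0653061224489796
k_ldh_f_a = 20.0
k_ldh_r_a = 0.22539682539682543

[mitochondria]
V_mito_n = 0.08704       # oxidative lump Vmax, mM/s
V_mito_a = 0.028558222222222224
K_pyr = 0.05             # mM
K_o2 = 0.02              # mM
K_adp = 0.1              # mM
n_atp_ox = 14.8          # ATP per pyruvate through the oxidative lump
o2_per_pyr = 3.0         # O2 equivalents consumed per pyruvate

[nadh_shuttle]
k_shuttle_n = 1.6        # cytosolic -> mitochondrial NADH shuttle, 1/s
k_shuttle_a = 0.10666666666666666

[sodium]
k_pump = 0.008           # Na/K-ATPase, 1/(mM s); ATP flux = k_pump*ATP*Na
g_leak_n = 0.5478        # constant Na leak influx, mM/s
g_leak_a = 0.1956
g_ampa = 2.0             # max AMPA Na influx, mM/s (neuron frame)
K_ampa = 0.05            # AMPA glutamate affinity, mM

[glutamate]
V_eaat = 1.0             # EAAT uptake Vmax, mM/s (ECS frame)
K_glu = 0.05             # EAAT affinity, mM
s_na = 3.0               # Na co-transported per glutamate
k_glu_decay = 0.5        # residual ECS glutamate clearance, 1/s
f_glu_recycle = 0.0      # cleared-glutamate fraction fed back to release

[creatine_kinase]
k_ck_f = 0.5             # PCr + ADP -> Cr + ATP, 1/(mM s)
k_ck_r = 0.06550802139037433

[glycogen]
V_gs = 0.01              # glycogen synthase Vmax, mM/s
K_gs = 0.5               # G6P affinity, mM
GLY_max = 14.0           # glycogen cap (synthase product inhibition), mM
V_gp = 0.05              # glycogen phosphorylase Vmax, mM/s
K_gp = 2.0               # glycogen affinity, mM
K_camp = 0.1             # cAMP activation constant of phosphorylase, uM

[noradrenaline]
k_ne = 1.0               # NE -> cAMP production gain, 1/s
k_camp_deg = 0.5         # cAMP degradation, 1/s

[capillary]
PS_o2 = 0.006            # O2 permeability-surface product, 1/s
GLC_art = 5.25           # arterial glucose, mM
LAC_art = 0.68           # arterial lactate, mM
O2_art = 10.84           # arterial O2 content, mM
F_0 = 0.05               # baseline capillary turnover rate, 1/s

[volumes]
v_n = 0.45               # neuron volume fraction
v_a = 0.25               # astrocyte
v_e = 0.20               # extracellular space
v_c = 0.10               # capillary

[flags]
disable_transport = false    # zero all trans-membrane + capillary exchange
disable_oxidation = false    # zero the mitochondrial lump

# Resting state consistent with the parameters above (balance-designed;
# also used as the root-finder initial guess).
[resting_state]
Na_n = 10.375
GLC_n = 1.0
G6P_n = 0.7
PYR_n = 0.15
LAC_n = 1.0
NADHc_n = 0.01
NADHm_n = 0.125
ATP_n = 2.2
PCr_n = 4.9
O2_n = 1.0
Na_a = 3.7045454545454546
GLC_a = 1.2
G6P_a = 0.9146666666666665
PYR_a = 0.15
LAC_a = 1.4
NADHc_a = 0.05
NADHm_a = 0.125
ATP_a = 2.2
PCr_a = 4.9
O2_a = 5.0
GLY_a = 14.0
cAMP_a = 0.0
GLU_e = 0.0
GLC_e = 2.0
LAC_e = 1.2
GLC_c = 4.5
LAC_c = 0.9
O2_c = 7.0
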