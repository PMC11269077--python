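procedure,unadjusted_pct,model_based_pct,risk_category
ASD hybrid repair (off pump),0.0,0.46,1
ASD secundum repair,0.18,0.13,1
ASD secundum repair (patch),0.07,0.14,1
AVSD repair - depression,0.77,0.42,1
AVSD repair - single patch,0.86,0.39,1
Aortic valvuloplasty,0.92,0.4,1
Coronary art. fistula repair,0.0,0.5,1
Cortraitriatum repair,0.0,0.5,1
Mitral valvuloplasty,1.52,0.85,1
PAPVD isolated repair,0.0,0.37,1
Pulm. Infundibulum resection (indirect),0.0,0.31,1
Subaortic fibromyectomy,0.0,0.32,1
Subaortic myectomy,1.25,0.52,1
Tricuspid valvuloplasty,0.56,0.77,1
VSD canal type repair,0.0,0.33,1
VSD membranous repair,0.29,0.33,1
VSD subarterial repair,0.06,0.12,1
Vascular ring repair,0.0,0.37,1
A-P window repair,3.23,0.79,2
A-V fistula repair,16.67,1.53,2
ASD common atrium repair,0.0,1.27,2
ASD repair - minimal invasive & CPB,0.0,0.81,2
ASD sinus venosus repair,0.0,0.67,2
Aortic valvotomy,0.0,0.61,2
Asc. aorta patch aortoplasty,3.26,1.97,2
Coarct repair - bypass or tubular graft,0.0,1.53,2
Coarct. repair - resection & E to S,2.65,1.64,2
Coarct. repair - patch aortoplasty,1.58,1.92,2
DORV repair - IVR,3.2,3.09,2
Ebstein anomaly repair,0.94,1.17,2
Excision of cardiac tumor,2.08,2.39,2
Exicion of intracardiac vegetation,0.0,1.22,2
Fontan operation - I stage,3.64,2.97,2
Hemitruncus repair,0.0,1.02,2
PDA closure (CPB),0.0,0.82,2
PDA closure (off pump),1.55,1.62,2
Pacemaker - re-implant,0.0,1.34,2
Pericardectomy,0.0,0.99,2
Pericardial drainage,5.0,3.26,2
Pulm. Infundibulum incision & resection,2.17,1.99,2
Pulmonary art. sling repair,0.0,0.96,2
Pulmonary art. stent,0.0,1.17,2
Pulmonary arterioplasty,3.19,3.42,2
Pulmonary valvotomy,1.5,1.29,2
Pulmonary valvotomy - hybrid,0.0,1.43,2
Subaortic septal patch (Konno),0.0,1.05,2
Supravalve mitral ring resection,0.0,0.79,2
Systemic vein repair,0.0,1.12,2
TAPVD repair - intracardiac,1.09,1.32,2
TAPVD repair - mixed type,2.94,2.67,2
Tetralogy repair,1.92,1.95,2
Tricuspid replacement (mech.),0.0,1.17,2
VSD Hybrid repair (off pump),0.58,0.84,2
VSD hybrid repair (CPB),0.0,0.99,2
VSD multiple repair,1.57,1.75,2
VSD muscular repair,0.95,1.2,2
VSD repair - minimal invasive & CPB,0.0,0.71,2
AVSD repair - two patches,5.58,5.27,3
Ao translocation operation,11.76,4.6,3
Aortic arch repair,7.14,6.3,3
Aortic valve replacement (mech.),6.67,4.46,3
Cavopulmonary shunt - bilateral,5.88,4.61,3
DOLV repair,0.0,2.05,3
Delayed sternal closure,5.72,6.23,3
Double switch (Senning + Rastelli),0.0,1.8,3
Excision of cardiac diverticulum,0.0,1.53,3
Fontan operation - II stage,5.59,5.77,3
Kawashima procedure,0.0,2.05,3
Mitral replacement (mech.),11.46,7.86,3
PA banding,11.88,3.78,3
Pulm. infundibulum resection & patch,5.13,4.48,3
"Pulm. infundibulum resection, patch across annulus",5.14,6.09,3
Pulm. vein stenosis repair,5.0,5.0,3
Pulmonary atresia/IVS repair,10.53,4.87,3
Pulmonary atresia/VSD repair,5.9,6.24,3
Pulmonary valvotomy (off pump),5.56,4.6,3
Senning procedure,5.26,4.34,3
TAPVD repair - supracardiac,5.46,5.77,3
ALC-PA repair,17.24,14.97,4
Cavopulmonary shunt - left,13.25,12.68,4
Cavopulmonary shunt - right,9.75,10.85,4
Central shunt - with graft,21.05,11.02,4
Conduit RV - PA,18.06,13.98,4
Double Switch (Hemi-Mustard),16.67,9.32,4
Interrupted aortic arch repair,14.29,13.32,4
Interruption of bronchial collaterals,12.5,9.32,4
Pacemaker - primary implant,11.76,11.95,4
R.E.V. RV - PA connection,14.29,8.28,4
Rastelli operation,12.0,9.44,4
Rt. or lt. heart assist,37.5,9.32,4
TAPVD repair - infracardiac,13.95,14.74,4
Takedown previous shunt,9.09,6.8,4
Arterial switch repair,19.08,19.2,5
Atrial septectomy,33.33,27.36,5
Coronary artery repair,33.33,24.0,5
DKS connection,44.44,30.71,5
Double switch (Senning + ASO),33.33,18.03,5
Fontan takedown,55.56,41.71,5
Norwood operation,75.0,50.76,5
PA debanding,33.33,16.53,5
PA unifocalization,18.03,21.0,5
Truncus repair,21.21,20.44,5
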