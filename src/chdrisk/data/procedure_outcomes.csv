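procedure,cases,deaths,rachs_grade,stseacts_grade,note
ASD hybrid repair (off pump),87,0,2,2,
ASD secundum repair,551,1,1,1,
ASD secundum repair (patch),1338,1,1,1,
AVSD repair - depression,391,3,3,3,
AVSD repair - single patch,116,1,3,3,
Aortic valvuloplasty,109,1,2,2,
Coronary art. fistula repair,78,0,2,2,
Cortraitriatum repair,70,0,3,2,
Mitral valvuloplasty,461,7,3,2,
PAPVD isolated repair,115,0,1,1,
Pulm. Infundibulum resection (indirect),178,0,2,1,
Subaortic fibromyectomy,155,0,3,1,
Subaortic myectomy,80,1,3,1,
Tricuspid valvuloplasty,540,3,3,2,
VSD canal type repair,154,0,3,1,
VSD membranous repair,7910,23,2,1,
VSD subarterial repair,1641,1,2,1,
Vascular ring repair,132,0,2,1,
A-P window repair,31,1,2,2,
A-V fistula repair,6,1,2,2,
ASD common atrium repair,9,0,2,2,
ASD repair - minimal invasive & CPB,29,0,2,2,
ASD sinus venosus repair,38,0,1,2,
Aortic valvotomy,56,0,2,2,
Asc. aorta patch aortoplasty,184,6,2,2,
Coarct repair - bypass or tubular graft,4,0,1,1,
Coarct. repair - resection & E to S,377,10,2,2,grade listed as 1/2; higher stored
Coarct. repair - patch aortoplasty,253,4,2,3,grade listed as 1/2; higher stored
DORV repair - IVR,375,12,3,4,
Ebstein anomaly repair,106,1,3,4,
Excision of cardiac tumor,96,2,3,4,
Exicion of intracardiac vegetation,11,0,2,2,
Fontan operation - I stage,110,4,3,2,
Hemitruncus repair,21,0,4,2,
PDA closure (CPB),32,0,1,2,
PDA closure (off pump),386,6,1,2,
Pacemaker - re-implant,8,0,1,1,
Pericardectomy,20,0,1,2,
Pericardial drainage,160,8,1,4,
Pulm. Infundibulum incision & resection,46,1,2,1,
Pulmonary art. sling repair,20,0,3,3,
Pulmonary art. stent,13,0,2,2,
Pulmonary arterioplasty,251,8,2,2,
Pulmonary valvotomy,200,3,2,2,
Pulmonary valvotomy - hybrid,5,0,2,2,
Subaortic septal patch (Konno),15,0,4,3,
Supravalve mitral ring resection,28,0,3,2,
Systemic vein repair,14,0,2,3,
TAPVD repair - intracardiac,184,2,4,4,grade listed as 2/4; higher stored
TAPVD repair - mixed type,34,1,4,4,grade listed as 2/4; higher stored
Tetralogy repair,2392,46,2,2,
Tricuspid replacement (mech.),13,0,3,2,
VSD Hybrid repair (off pump),171,1,2,2,
VSD hybrid repair (CPB),21,0,2,2,
VSD multiple repair,127,2,2,2,
VSD muscular repair,105,1,2,1,
VSD repair - minimal invasive & CPB,45,0,2,2,
AVSD repair - two patches,269,15,3,3,
Ao translocation operation,17,2,3,3,
Aortic arch repair,70,5,4,4,
Aortic valve replacement (mech.),45,3,3,1,
Cavopulmonary shunt - bilateral,102,6,2,2,
DOLV repair,4,0,3,4,
Delayed sternal closure,891,51,1,1,
Double switch (Senning + Rastelli),3,0,4,5,
Excision of cardiac diverticulum,4,0,2,2,
Fontan operation - II stage,537,30,3,2,
Kawashima procedure,4,0,3,1,
Mitral replacement (mech.),96,11,3,4,
PA banding,101,12,3,4,
Pulm. infundibulum resection & patch,78,4,2,1,
"Pulm. infundibulum resection, patch across annulus",292,15,2,2,
Pulm. vein stenosis repair,40,2,4,4,
Pulmonary atresia/IVS repair,19,2,4,3,
Pulmonary atresia/VSD repair,288,17,4,3,
Pulmonary valvotomy (off pump),18,1,2,2,
Senning procedure,19,1,3,4,
TAPVD repair - supracardiac,238,13,4,4,grade listed as 2/4; higher stored
ALC-PA repair,58,10,3,2,
Cavopulmonary shunt - left,83,11,2,1,
Cavopulmonary shunt - right,359,35,2,1,
Central shunt - with graft,38,8,3,4,
Conduit RV - PA,72,13,2,3,
Double Switch (Hemi-Mustard),6,1,4,5,
Interrupted aortic arch repair,77,11,5,4,
Interruption of bronchial collaterals,8,1,1,2,
Pacemaker - primary implant,17,2,1,1,
R.E.V. RV - PA connection,7,1,4,3,
Rastelli operation,50,6,4,3,
Rt. or lt. heart assist,8,3,2,1,
TAPVD repair - infracardiac,43,6,4,4,grade listed as 2/4; higher stored
Takedown previous shunt,11,1,2,3,
Arterial switch repair,456,87,3,3,
Atrial septectomy,12,4,4,4,
Coronary artery repair,6,2,3,2,
DKS connection,9,4,6,5,
Double switch (Senning + ASO),18,6,4,5,
Fontan takedown,9,5,3,3,
Norwood operation,4,3,6,5,
PA debanding,3,1,3,4,
PA unifocalization,61,11,4,4,
Truncus repair,33,7,4,4,
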