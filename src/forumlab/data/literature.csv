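study,study_n,test,mean,sd,unit,cycle_phase,fasting,printed_label
diamanti_kandarakis,634,age,24.3,5.6,years,Follicular,Fasting,a
cai,600,age,27.7,5.2,years,Early Follicular,Fasting,a
tosi,375,age,23.1,5.3,years,Not Specified,Fasting,b
paschou,372,age,25.5,6.1,years,Early Follicular,Fasting,a
sova,319,age,28.1,4.3,years,Early Follicular,Fasting,c
kumar,213,age,27.5,6.6,years,Follicular,Fasting,a
bahceci,98,age,22.4,3.5,years,Follicular,Fasting,b
homburg,90,age,31.6,4.4,years,Early Follicular,Not Specified,c
pigny,73,age,29,4.4,years,Early Follicular,Not Specified,c
wright,69,age,24.8,6.2,years,Early Follicular,Fasting,a
diamanti_kandarakis,634,total_t,79,28.9,ng/dL,Follicular,Fasting,c
cai,600,total_t,64.9,26.8,ng/dL,Early Follicular,Fasting,a
paschou,372,total_t,85.8,36.5,ng/dL,Early Follicular,Fasting,c
sova,319,total_t,46.2,20.2,ng/dL,Early Follicular,Fasting,a
kumar,213,total_t,99.7,89.2,ng/dL,Follicular,Fasting,c
bahceci,98,total_t,99,35,ng/dL,Follicular,Fasting,c
pigny,73,total_t,45,21.6,ng/dL,Early Follicular,Not Specified,b
wright,69,total_t,50,25.3,ng/dL,Early Follicular,Fasting,a
diamanti_kandarakis,634,dheas,286.3,119.8,ug/dL,Follicular,Fasting,b
paschou,372,dheas,288.3,127.4,ug/dL,Early Follicular,Fasting,b
kumar,213,dheas,163.9,83.4,ug/dL,Follicular,Fasting,b
wright,69,dheas,265.3,118.3,ug/dL,Early Follicular,Fasting,b
diamanti_kandarakis,634,bmi,26.7,7.4,kg/m2,Follicular,Fasting,a
cai,600,bmi,26.4,5.7,kg/m2,Early Follicular,Fasting,a
tosi,375,bmi,27.6,7.1,kg/m2,Not Specified,Fasting,c
paschou,372,bmi,27.8,7,kg/m2,Early Follicular,Fasting,c
sova,319,bmi,27.3,6.3,kg/m2,Early Follicular,Fasting,c
kumar,213,bmi,36,9.2,kg/m2,Follicular,Fasting,c
bahceci,98,bmi,23.5,5.9,kg/m2,Follicular,Fasting,a
homburg,90,bmi,24.9,2.4,kg/m2,Early Follicular,Not Specified,a
pigny,73,bmi,26,6.1,kg/m2,Early Follicular,Not Specified,a
wright,69,bmi,21.9,2.1,kg/m2,Early Follicular,Fasting,b
cai,600,free_t,13.7,7.3,pg/mL,Early Follicular,Fasting,c
kumar,213,free_t,9.2,5.8,pg/mL,Follicular,Fasting,c
bahceci,98,free_t,1.9,1.1,pg/mL,Follicular,Fasting,b
diamanti_kandarakis,634,fpg,96.8,13.7,mg/dL,Follicular,Fasting,a
tosi,375,fpg,85.1,10,mg/dL,Not Specified,Fasting,b
paschou,372,fpg,83.1,7.8,mg/dL,Early Follicular,Fasting,b
sova,319,fpg,91.8,9,mg/dL,Early Follicular,Fasting,a
kumar,213,fpg,88,12.3,mg/dL,Follicular,Fasting,b
bahceci,98,fpg,90.5,9.2,mg/dL,Follicular,Fasting,a
wright,69,fpg,80.8,8.6,mg/dL,Early Follicular,Fasting,b
diamanti_kandarakis,634,fsh,5.5,1.7,U/L,Follicular,Fasting,a
cai,600,fsh,6.23,2.5,U/L,Early Follicular,Fasting,a
sova,319,fsh,6.2,2.1,U/L,Early Follicular,Fasting,a
bahceci,98,fsh,6.9,5.6,U/L,Follicular,Fasting,a
homburg,90,fsh,5.1,1.4,U/L,Early Follicular,Not Specified,a
pigny,73,fsh,5.5,1.6,U/L,Early Follicular,Not Specified,a
wright,69,fsh,5.8,3.2,U/L,Early Follicular,Fasting,a
diamanti_kandarakis,634,lh,7.9,5.7,U/L,Follicular,Fasting,b
cai,600,lh,8.8,6.4,U/L,Early Follicular,Fasting,b
sova,319,lh,6.9,4.8,U/L,Early Follicular,Fasting,b
bahceci,98,lh,7.6,5,U/L,Follicular,Fasting,b
homburg,90,lh,8.8,5.2,U/L,Early Follicular,Not Specified,b
pigny,73,lh,6.7,4,U/L,Early Follicular,Not Specified,b
wright,69,lh,16.6,9.7,U/L,Early Follicular,Fasting,a
cai,600,tsh,2.3,1.2,mU/L,Early Follicular,Fasting,a
bahceci,98,tsh,1.7,1.18,mU/L,Follicular,Fasting,b
wright,69,tsh,2.5,1,mU/L,Early Follicular,Fasting,a
bahceci,98,prl,24.7,17.1,ng/mL,Follicular,Fasting,a
wright,69,prl,16.6,9.7,ng/mL,Early Follicular,Fasting,b
diamanti_kandarakis,634,fi,13.3,14.4,mU/L,Follicular,Fasting,a
tosi,375,fi,15.7,11.8,mU/L,Not Specified,Fasting,a
paschou,372,fi,15.2,4.8,mU/L,Early Follicular,Fasting,a
sova,319,fi,11.2,11.5,mU/L,Early Follicular,Fasting,a
kumar,213,fi,19.7,14.7,mU/L,Follicular,Fasting,c
bahceci,98,fi,10.2,6.2,mU/L,Follicular,Fasting,a
wright,69,fi,11.3,6.9,mU/L,Early Follicular,Fasting,a
diamanti_kandarakis,634,shbg,38,20.6,nmol/L,Follicular,Fasting,b
paschou,372,shbg,31.5,12.5,nmol/L,Early Follicular,Fasting,b
sova,319,shbg,50.9,27.7,nmol/L,Early Follicular,Fasting,b
bahceci,98,shbg,115,38,nmol/L,Follicular,Fasting,c
sova,319,amh,9.3,6.6,ng/mL,Early Follicular,Fasting,a
homburg,90,amh,10.9,8.5,ng/mL,Early Follicular,Not Specified,a
pigny,73,amh,11.4,8,ng/mL,Early Follicular,Not Specified,a
tosi,375,homa_ir,3.4,2.8,index,Not Specified,Fasting,c
paschou,372,homa_ir,3.1,1.9,index,Early Follicular,Fasting,c
sova,319,homa_ir,2.6,2.8,index,Early Follicular,Fasting,a
wright,69,homa_ir,2.3,1.5,index,Early Follicular,Fasting,a
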