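equation_id,display_name,sex,age_lo,age_hi,intercept,coef_weight,coef_height,coef_age,height_unit,output_unit
harris_benedict,Harris-Benedict,male,0,inf,66.473,13.7516,5.0033,-6.755,cm,kcal_d
harris_benedict,Harris-Benedict,female,0,inf,655.0955,9.5634,1.8496,-4.6756,cm,kcal_d
who_wt,WHO-Wt,male,0,3,-54,60.9,0,0,cm,kcal_d
who_wt,WHO-Wt,male,3,10,495,22.7,0,0,cm,kcal_d
who_wt,WHO-Wt,male,10,18,651,17.5,0,0,cm,kcal_d
who_wt,WHO-Wt,male,18,inf,679,15.3,0,0,cm,kcal_d
who_wt,WHO-Wt,female,0,3,-51,61.0,0,0,cm,kcal_d
who_wt,WHO-Wt,female,3,10,499,22.5,0,0,cm,kcal_d
who_wt,WHO-Wt,female,10,18,746,12.2,0,0,cm,kcal_d
who_wt,WHO-Wt,female,18,inf,496,14.7,0,0,cm,kcal_d
schofield_wt,Schofield-Wt,male,0,3,-30.4,59.512,0,0,cm,kcal_d
schofield_wt,Schofield-Wt,male,3,10,504.3,22.706,0,0,cm,kcal_d
schofield_wt,Schofield-Wt,male,10,18,658.2,17.686,0,0,cm,kcal_d
schofield_wt,Schofield-Wt,male,18,inf,692.2,15.057,0,0,cm,kcal_d
schofield_wt,Schofield-Wt,female,0,3,-31.1,58.317,0,0,cm,kcal_d
schofield_wt,Schofield-Wt,female,3,10,485.9,20.315,0,0,cm,kcal_d
schofield_wt,Schofield-Wt,female,10,18,692.6,13.384,0,0,cm,kcal_d
schofield_wt,Schofield-Wt,female,18,inf,486.6,14.818,0,0,cm,kcal_d
schofield_wt_ht,Schofield-Wt&Ht,male,0,3,-617.6,0.167,1517.4,0,m,kcal_d
schofield_wt_ht,Schofield-Wt&Ht,male,3,10,414.9,19.59,130.3,0,m,kcal_d
schofield_wt_ht,Schofield-Wt&Ht,male,10,18,515.5,16.25,137.2,0,m,kcal_d
schofield_wt_ht,Schofield-Wt&Ht,male,18,inf,717,15.4,-27,0,m,kcal_d
schofield_wt_ht,Schofield-Wt&Ht,female,0,3,-413.5,16.252,1023.2,0,m,kcal_d
schofield_wt_ht,Schofield-Wt&Ht,female,3,10,371.2,16.969,161.8,0,m,kcal_d
schofield_wt_ht,Schofield-Wt&Ht,female,10,18,200,8.365,465,0,m,kcal_d
schofield_wt_ht,Schofield-Wt&Ht,female,18,inf,35,13.3,334,0,m,kcal_d
henry,Henry,male,0,3,-0.141,0.255,0,0,cm,mj_d
henry,Henry,male,3,10,2.15,0.0937,0,0,cm,mj_d
henry,Henry,male,10,18,2.43,0.0769,0,0,cm,mj_d
henry,Henry,male,18,inf,2.28,0.0669,0,0,cm,mj_d
henry,Henry,female,0,3,-0.0965,0.246,0,0,cm,mj_d
henry,Henry,female,3,10,2.12,0.0842,0,0,cm,mj_d
henry,Henry,female,10,18,3.18,0.0465,0,0,cm,mj_d
henry,Henry,female,18,inf,2.33,0.0546,0,0,cm,mj_d
iom_nw,IOM NW,male,0,inf,68,19.2,712,-43.3,m,kcal_d
iom_nw,IOM NW,female,0,inf,189,7.9,625,-17.6,m,kcal_d
iom_ow_ob,IOM OW and OB,male,0,inf,420,16.7,418.9,-33.5,m,kcal_d
iom_ow_ob,IOM OW and OB,female,0,inf,516,12.4,347,-26.8,m,kcal_d
molnar,Molnar,male,0,inf,0.0269,0.0509,0.0253,-0.0503,cm,mj_d
molnar,Molnar,female,0,inf,1.6298,0.0512,0.0245,-0.2075,cm,mj_d
muller,Muller,male,0,inf,-0.497,0.02606,0.04129,-0.08369,cm,mj_d
muller,Muller,female,0,inf,-0.808,0.02606,0.04129,-0.08369,cm,mj_d
mifflin,Mifflin,male,0,inf,5,10,6.25,-5,cm,kcal_d
mifflin,Mifflin,female,0,inf,-161,10,6.25,-5,cm,kcal_d
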