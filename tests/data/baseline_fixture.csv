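format_version,1
device,tomodose-like-223
timestamp,2024-01-01T07:30:00
plan,dailyqa-default
shift_mm,0,0,0
output_scale,1
axis,position_mm,dose_cGy
X,-200.0,3.4658582341029264e-47
X,-196.0,6.871962519775537e-41
X,-192.0,5.012521954904135e-35
X,-188.0,1.3450465400052845e-29
X,-184.0,1.3277730624197739e-24
X,-180.0,4.821874619909795e-20
X,-176.0,6.441892772887453e-16
X,-172.0,3.166041387273544e-12
X,-168.0,5.724337114113882e-09
X,-164.0,3.807494936178157e-06
X,-160.0,0.0009316632930196678
X,-156.0,0.08386565697562796
X,-152.0,2.7772491345605763
X,-148.0,33.833820809153174
X,-144.0,151.63266492815836
X,-140.0,250.0
X,-136.0,151.63266492815836
X,-132.0,33.833820809156215
X,-128.0,2.77724914005594
X,-124.0,0.0838693121707667
X,-120.0,0.0018260600543185488
X,-116.0,0.08051483819153903
X,-112.0,2.6661591749024907
X,-108.0,32.480467976790216
X,-104.0,145.567358331032
X,-100.0,240.0
X,-96.0,145.567358331032
X,-92.0,32.48046797678705
X,-88.0,2.6661591691781537
X,-84.0,0.08051103069660284
X,-80.0,0.000894396761298881
X,-76.0,3.655195138731031e-06
X,-72.0,12.360000005495264
X,-68.0,92.36000000000294
X,-66.0,132.35999999999996
X,-64.0,172.3599999999999
X,-62.0,200.0
X,-60.0,200.0
X,-58.0,200.0
X,-56.0,200.0
X,-54.0,200.0
X,-52.0,200.0
X,-50.0,200.0
X,-48.0,200.0
X,-46.0,200.0
X,-44.0,200.0
X,-42.0,200.00000000000006
X,-40.0,200.00000000000134
X,-38.0,200.00000000003004
X,-36.0,200.00000000057958
X,-34.0,200.00000000953105
X,-32.0,200.0000001335607
X,-30.0,200.00000159488349
X,-28.0,200.00001622901485
X,-26.0,200.00014072402172
X,-24.0,200.0010398176909
X,-22.0,200.0065472518753
X,-20.0,200.03512964639395
X,-18.0,200.16062065433886
X,-16.0,200.625809117565
X,-14.0,202.07775944163046
X,-12.0,205.8784323639905
X,-10.0,214.1723108605381
X,-8.0,229.1160661034585
X,-6.0,250.97269624412826
X,-4.0,276.04232716235697
X,-2.0,296.66874379360854
X,0.0,304.72
X,2.0,296.66874379360854
X,4.0,276.04232716235697
X,6.0,250.97269624412826
X,8.0,229.1160661034585
X,10.0,214.1723108605381
X,12.0,205.8784323639905
X,14.0,202.07775944163046
X,16.0,200.625809117565
X,18.0,200.16062065433886
X,20.0,200.03512964639395
X,22.0,200.0065472518753
X,24.0,200.0010398176909
X,26.0,200.00014072402172
X,28.0,200.00001622901485
X,30.0,200.00000159488349
X,32.0,200.0000001335607
X,34.0,200.00000000953105
X,36.0,200.00000000057958
X,38.0,200.00000000003004
X,40.0,200.00000000000134
X,42.0,200.00000000000006
X,44.0,200.0
X,46.0,200.0
X,48.0,200.0
X,50.0,200.0
X,52.0,200.0
X,54.0,200.0
X,56.0,200.0
X,58.0,200.0
X,60.0,200.0
X,62.0,200.0
X,64.0,172.3599999999999
X,66.0,132.35999999999996
X,68.0,92.36000000000294
X,72.0,12.360000005495264
X,76.0,3.655195138731031e-06
X,80.0,0.000894396761298881
X,84.0,0.08051103069660284
X,88.0,2.6661591691781537
X,92.0,32.48046797678705
X,96.0,145.567358331032
X,100.0,240.0
X,104.0,145.567358331032
X,108.0,32.480467976790216
X,112.0,2.6661591749024907
X,116.0,0.08051483819153903
X,120.0,0.0018260600543185488
X,124.0,0.0838693121707667
X,128.0,2.77724914005594
X,132.0,33.833820809156215
X,136.0,151.63266492815836
X,140.0,250.0
X,144.0,151.63266492815836
X,148.0,33.833820809153174
X,152.0,2.7772491345605763
X,156.0,0.08386565697562796
X,160.0,0.0009316632930196678
X,164.0,3.807494936178157e-06
X,168.0,5.724337114113882e-09
X,172.0,3.166041387273544e-12
X,176.0,6.441892772887453e-16
X,180.0,4.821874619909795e-20
X,184.0,1.3277730624197739e-24
X,188.0,1.3450465400052845e-29
X,192.0,5.012521954904135e-35
X,196.0,6.871962519775537e-41
X,200.0,3.4658582341029264e-47
Y,-104.0,0.06709252558050237
Y,-100.0,2.2217993076484617
Y,-96.0,27.067056647325327
Y,-92.0,121.30613194756411
Y,-88.0,200.00000335059553
Y,-84.0,121.30695180622455
Y,-80.0,27.140858425461094
Y,-76.0,4.665778546061769
Y,-72.0,29.8408548376353
Y,-68.0,133.43749046741377
Y,-66.0,194.14937256018104
Y,-64.0,220.00000304599595
Y,-62.0,194.14931870244268
Y,-60.0,133.43674514135884
Y,-58.0,71.42354281895899
Y,-56.0,29.77376231205733
Y,-54.0,9.666125397149672
Y,-52.0,2.443979238413308
Y,-50.0,0.48124804600023474
Y,-48.0,0.07380177813855261
Y,-46.0,0.008814365426449235
Y,-44.0,0.0008198636978573076
Y,-42.0,52.500059390727074
Y,-40.0,112.50000335059555
Y,-38.0,172.5000001472149
Y,-36.0,232.5000000050374
Y,-34.0,292.50000000013426
Y,-32.0,300.0000000000028
Y,-30.0,300.00000000000006
Y,-28.0,300.0
Y,-26.0,300.0
Y,-24.0,300.0
Y,-22.0,300.0
Y,-20.0,300.0
Y,-18.0,300.0
Y,-16.0,300.0
Y,-14.0,300.0
Y,-12.0,300.0
Y,-10.0,300.0
Y,-8.0,300.0
Y,-6.0,300.0
Y,-4.0,300.0
Y,-2.0,300.0
Y,0.0,300.0
Y,2.0,300.0
Y,4.0,300.0
Y,6.0,300.0
Y,8.0,300.0
Y,10.0,300.0
Y,12.0,300.0
Y,14.0,300.0
Y,16.0,300.0
Y,18.0,300.0
Y,20.0,300.0
Y,22.0,300.0
Y,24.0,300.0
Y,26.0,300.0
Y,28.0,300.0
Y,30.0,300.00000000000006
Y,32.0,300.0000000000028
Y,34.0,292.50000000013426
Y,36.0,232.5000000050374
Y,38.0,172.5000001472149
Y,40.0,112.50000335059555
Y,42.0,52.500059390727074
Y,44.0,0.0008198636978573076
Y,46.0,0.008814365426449235
Y,48.0,0.07380177813855261
Y,50.0,0.48124804600023474
Y,52.0,2.443979238413308
Y,54.0,9.666125397149672
Y,56.0,29.77376231205733
Y,58.0,71.42354281895899
Y,60.0,133.43674514135884
Y,62.0,194.14931870244268
Y,64.0,220.00000304599595
Y,66.0,194.14937256018104
Y,68.0,133.43749046741377
Y,72.0,29.8408548376353
Y,76.0,4.665778546061769
Y,80.0,27.140858425461094
Y,84.0,121.30695180622455
Y,88.0,200.00000335059553
Y,92.0,121.30613194756411
Y,96.0,27.067056647325327
Y,100.0,2.2217993076484617
Y,104.0,0.06709252558050237
Y,108.0,0.0007453306344157341
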