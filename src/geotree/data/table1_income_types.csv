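country,income_type
Afghanistan,I
Benin,I
Burkina Faso,I
Burundi,I
Central African Republic,I
Chad,I
Democratic Republic of the Congo,I
Eritrea,I
Ethiopia,I
Gambia,I
Guinea,I
Guinea-Bissau,I
Liberia,I
Madagascar,I
Malawi,I
Mali,I
Mozambique,I
Nepal,I
Niger,I
Rwanda,I
Senegal,I
Sierra Leone,I
Togo,I
Uganda,I
United Republic of Tanzania,I
Zimbabwe,I
Angola,II
Armenia,II
Bangladesh,II
Bhutan,II
Bolivia (Plurinational State of),II
Cabo Verde,II
Cambodia,II
Cameroon,II
Congo,II
Côte d'Ivoire,II
Djibouti,II
Egypt,II
El Salvador,II
Eswatini,II
Georgia,II
Ghana,II
Guatemala,II
Honduras,II
India,II
Indonesia,II
Jordan,II
Kenya,II
Kiribati,II
Kyrgyzstan,II
Lao People's Democratic Republic,II
Lesotho,II
Mauritania,II
Micronesia (Federated States of),II
Mongolia,II
Morocco,II
Myanmar,II
Nicaragua,II
Nigeria,II
Pakistan,II
Papua New Guinea,II
Philippines,II
Republic of Moldova,II
Sao Tome and Principe,II
Solomon Islands,II
Sri Lanka,II
Sudan,II
Tajikistan,II
Timor-Leste,II
Tunisia,II
Ukraine,II
Uzbekistan,II
Vanuatu,II
Viet Nam,II
Yemen,II
Zambia,II
Albania,III
Algeria,III
Argentina,III
Azerbaijan,III
Belarus,III
Belize,III
Bosnia and Herzegovina,III
Botswana,III
Brazil,III
Bulgaria,III
China,III
Colombia,III
Costa Rica,III
Croatia,III
Cuba,III
Dominican Republic,III
Ecuador,III
Equatorial Guinea,III
Fiji,III
Gabon,III
Grenada,III
Guyana,III
Iran (Islamic Republic of),III
Iraq,III
Jamaica,III
Kazakhstan,III
Lebanon,III
Libya,III
Malaysia,III
Maldives,III
Mauritius,III
Mexico,III
Montenegro,III
Namibia,III
Panama,III
Paraguay,III
Peru,III
Republic of North Macedonia,III
Romania,III
Russian Federation,III
Saint Lucia,III
Saint Vincent and the Grenadines,III
Samoa,III
Serbia,III
South Africa,III
Suriname,III
Thailand,III
Tonga,III
Turkey,III
Turkmenistan,III
Venezuela (Bolivarian Republic of),III
Antigua and Barbuda,IV
Australia,IV
Austria,IV
Bahamas,IV
Bahrain,IV
Barbados,IV
Belgium,IV
Brunei Darussalam,IV
Canada,IV
Chile,IV
Cyprus,IV
Czechia,IV
Denmark,IV
Estonia,IV
Finland,IV
France,IV
Germany,IV
Greece,IV
Hungary,IV
Iceland,IV
Ireland,IV
Israel,IV
Italy,IV
Japan,IV
Kuwait,IV
Latvia,IV
Lithuania,IV
Luxembourg,IV
Malta,IV
Netherlands,IV
New Zealand,IV
Norway,IV
Oman,IV
Poland,IV
Portugal,IV
Republic of Korea,IV
Saudi Arabia,IV
Seychelles,IV
Singapore,IV
Slovakia,IV
Slovenia,IV
Spain,IV
Sweden,IV
Switzerland,IV
Trinidad and Tobago,IV
United Arab Emirates,IV
United Kingdom of Great Britain and Northern Ireland,IV
United States of America,IV
Uruguay,IV
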