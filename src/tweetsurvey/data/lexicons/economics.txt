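; Starter economics vocabulary (run input in production; bundled for tests
; and the synthetic generator).
economy
economics
economic
market
markets
stock
stocks
trade
tariff
inflation
recession
unemployment
jobs
gdp
finance
financial
bank
banking
investment
investor
currency
dollar
euro
tax
taxes
budget
deficit
debt
interest rate
wage
wages
salary
income
business
industry
manufacturing
export
import
retail
commerce
entrepreneur
startup
revenue
profit
stimulus
bailout
mortgage
bitcoin
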